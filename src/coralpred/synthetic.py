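"""Synthetic feeding trials and presence/absence surveys with known truth.

Two generators emulate the study designs this package analyses:

* a closed-arena feeding assay — two hawkfish size classes crossed with
  prey densities {2, 4, 6} over 72 h (T = 3 days), 20 trials in total.
  The published account of the assay gives two slightly different replicate
  layouts (its tabulated set-up and its narrative description disagree);
  both are shipped, with the tabulated layout as the default.
* a coral-head survey — heads assigned a predator category
  (none / small / large) and, per prey species, a Bernoulli presence flag
  whose probability depends on the category.

Trial outcomes can be drawn two ways: ``binomial`` mode draws consumed
counts from Binomial(n0, Ne/n0) with Ne the random-predator expectation —
exactly the likelihood the fitter assumes — while ``mechanistic`` mode runs
an event-driven search-and-handle renewal process (exponential search at
rate a*N_current, a handling period per capture, no prey replacement) whose
deterministic approximation is the random predator equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cooccur import CATEGORIES, SurveyTable
from .fr_core import FRParams, TrialContext, rogers_expected
from .fr_fit import Trial, TrialDataset

__all__ = [
    "DesignCell",
    "ExperimentDesign",
    "SurveyGenSpec",
    "assay_design",
    "simulate_trial",
    "simulate_experiment",
    "simulate_survey",
    "reference_survey_spec",
]


@dataclass(frozen=True)
class DesignCell:
    predator_class: str
    prey_density: int
    replicates: int

    def __post_init__(self):
        if self.prey_density < 1:
            raise ValueError("prey_density must be a positive integer")
        if self.replicates < 0:
            raise ValueError("replicates must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Replicate layout of a feeding assay: cells of
    (predator class, prey density, replicates) plus a common duration."""

    cells: tuple[DesignCell, ...]
    duration_days: float = 3.0

    @property
    def total_trials(self) -> int:
        return sum(c.replicates for c in self.cells)

    @property
    def total_prey(self) -> int:
        return sum(c.replicates * c.prey_density for c in self.cells)

    def scaled(self, factor: int) -> "ExperimentDesign":
        """Same layout with every cell's replicates multiplied by ``factor``."""
        return ExperimentDesign(
            cells=tuple(
                DesignCell(c.predator_class, c.prey_density, c.replicates * factor)
                for c in self.cells
            ),
            duration_days=self.duration_days,
        )


_TABULATED = {
    "small": {6: 5, 4: 4, 2: 3},
    "large": {6: 2, 4: 2, 2: 4},
}
_NARRATIVE = {
    "large": {2: 4, 4: 3, 6: 5},
    "small": {2: 4, 4: 2, 6: 2},
}


def assay_design(variant: str = "tabulated") -> ExperimentDesign:
    """The 20-trial hawkfish-chromis feeding-assay layout.

    ``variant="tabulated"`` is the tabulated set-up
    (small: 6x5, 4x4, 2x3; large: 6x2, 4x2, 2x4); ``variant="narrative"``
    is the layout from the narrative account
    (large: 2x4, 4x3, 6x5; small: 2x4, 4x2, 6x2).  Both total 20 trials at
    densities {2, 4, 6} over 3 days.
    """
    layouts = {"tabulated": _TABULATED, "narrative": _NARRATIVE}
    if variant not in layouts:
        raise ValueError(f"unknown design variant {variant!r}; use {sorted(layouts)}")
    cells = tuple(
        DesignCell(cls, density, reps)
        for cls, by_density in layouts[variant].items()
        for density, reps in by_density.items()
    )
    return ExperimentDesign(cells=cells, duration_days=3.0)


def simulate_trial(
    ctx: TrialContext,
    params: FRParams,
    mode: str = "binomial",
    rng: np.random.Generator | None = None,
    handling: str = "fixed",
) -> int:
    """Draw the consumed count of one feeding trial.

    ``binomial`` mode draws Binomial(n0, Ne/n0) — the fitter's exact
    data-generating process.  ``mechanistic`` mode simulates the predator's
    search-and-handle cycle: search times are exponential with rate
    a * (prey remaining); each capture is followed by a handling period of
    length h (``handling="fixed"``, matching the total-handling-time
    accounting behind the random predator equation) or Exponential(mean h)
    (``handling="exponential"``); captures completed before the horizon T
    are counted and prey are not replaced.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if mode == "binomial":
        p = rogers_expected(ctx, params) / ctx.n0
        return int(rng.binomial(ctx.n0, p))
    if mode != "mechanistic":
        raise ValueError(f"unknown simulation mode {mode!r}")
    if handling not in ("fixed", "exponential"):
        raise ValueError(f"unknown handling model {handling!r}")
    a, h = params.a, params.h
    if a == 0.0:
        return 0
    t = 0.0
    remaining = ctx.n0
    consumed = 0
    while remaining > 0:
        t += rng.exponential(1.0 / (a * remaining))
        if t > ctx.T:
            break
        consumed += 1
        remaining -= 1
        t += rng.exponential(h) if handling == "exponential" else h
    return consumed


def simulate_experiment(
    design: ExperimentDesign,
    params_by_class: dict[str, FRParams],
    mode: str = "binomial",
    seed: int = 0,
    handling: str = "fixed",
) -> TrialDataset:
    """Simulate one dataset from a replicate layout (one Trial per replicate)."""
    missing = {c.predator_class for c in design.cells} - set(params_by_class)
    if missing:
        raise ValueError(f"no parameters for predator classes {sorted(missing)}")
    rng = np.random.default_rng(seed)
    trials = []
    i = 0
    for cell in design.cells:
        ctx = TrialContext(n0=cell.prey_density, T=design.duration_days)
        params = params_by_class[cell.predator_class]
        for _ in range(cell.replicates):
            consumed = simulate_trial(ctx, params, mode=mode, rng=rng, handling=handling)
            trials.append(
                Trial(
                    trial_id=f"t{i:04d}",
                    predator_class=cell.predator_class,
                    n_initial=cell.prey_density,
                    n_consumed=consumed,
                    duration=design.duration_days,
                )
            )
            i += 1
    return TrialDataset(trials)


@dataclass(frozen=True)
class SurveyGenSpec:
    """Ground truth for a synthetic coral-head survey.

    ``category_probs``: multinomial probabilities of (none, small, large)
    occupancy per head.  ``presence_probs``: per species, the Bernoulli
    presence probability under each category, as
    {species: (p_none, p_small, p_large)}.
    """

    n_heads: int
    category_probs: tuple[float, float, float]
    presence_probs: dict[str, tuple[float, float, float]]
    seed: int = 0

    def __post_init__(self):
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or (probs > 1).any():
            raise ValueError("category_probs must be three probabilities")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("category_probs must sum to 1")
        for sp, ps in self.presence_probs.items():
            arr = np.asarray(ps, dtype=float)
            if arr.shape != (3,) or (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"presence_probs[{sp!r}] must be three probabilities")


def reference_survey_spec(seed: int = 0) -> SurveyGenSpec:
    """Survey generator mirroring the field study's structure: 67 heads with
    category frequencies (0.473, 0.333, 0.194) and presence probabilities
    chosen so prey are commoner on predator-free heads and the expected
    marginal presence matches the reported head counts (chromis on ~16/67
    heads, damselfish on ~23/67).

    The reported category percentages do not all correspond to integer
    counts out of 67 heads; the generator targets the percentages.
    """
    return SurveyGenSpec(
        n_heads=67,
        category_probs=(0.473, 0.333, 0.194),
        presence_probs={
            "chromis": (0.40, 0.10, 0.10),
            "dascyllus": (0.55, 0.15, 0.15),
        },
        seed=seed,
    )


def simulate_survey(spec: SurveyGenSpec) -> SurveyTable:
    """Draw a synthetic survey table from a :class:`SurveyGenSpec`.

    Categories are i.i.d. multinomial, presence flags Bernoulli per species
    given the head's category.  The generating spec is echoed in the table's
    metadata so downstream recovery checks know the truth.
    """
    rng = np.random.default_rng(spec.seed)
    cat_idx = rng.choice(3, size=spec.n_heads, p=np.asarray(spec.category_probs))
    cats = [CATEGORIES[i] for i in cat_idx]
    data = {"head_id": [f"head{i:03d}" for i in range(spec.n_heads)], "hawkfish": cats}
    for sp, ps in spec.presence_probs.items():
        p = np.asarray(ps)[cat_idx]
        data[f"{sp}_present"] = rng.binomial(1, p)
    frame = pd.DataFrame(data)
    return SurveyTable(
        data=frame,
        metadata={
            "generator": "coralpred.synthetic.simulate_survey",
            "seed": spec.seed,
            "category_probs": tuple(spec.category_probs),
            "presence_probs": {k: tuple(v) for k, v in spec.presence_probs.items()},
        },
    )
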