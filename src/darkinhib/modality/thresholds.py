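"""Derivation of categorical inhibition-level thresholds from density antimodes.

The species-level distribution of dark inhibition is multimodal; the
category boundaries are the antimodes (valleys) between the substantive
density peaks. The published boundaries (18, 44, 77 percent) correspond to
four substantive peaks; this module re-derives cutpoints from data and also
provides the published set as a constant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dip import dip_test
from .kde import KdeModes, kde_modes
from .silverman import silverman_test

#: The published category boundaries (percent dark inhibition).
PAPER_DEFAULT_CUTPOINTS: tuple[float, float, float] = (18.0, 44.0, 77.0)


@dataclass(frozen=True)
class ThresholdSet:
    cutpoints: tuple[float, ...]
    provenance: str  # "paper_default" | "derived"
    robustness_shift: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise ValueError("cutpoints must be strictly increasing")


PAPER_DEFAULT = ThresholdSet(cutpoints=PAPER_DEFAULT_CUTPOINTS, provenance="paper_default")


@dataclass(frozen=True)
class ModalityConfig:
    """Settings for the threshold-derivation pipeline.

    ``bandwidth`` defaults to the Sheather–Jones plug-in: the rule of thumb
    oversmooths multimodal densities and hides the peak structure the
    categories are built from. ``min_mode_mass`` is the smallest basin probability
    that counts as a substantive peak.
    """

    bandwidth: object = "sheather_jones"
    grid_points: int = 512
    min_mode_mass: float = 0.035
    k_max: int = 8
    n_restarts: int = 10
    em_tol: float = 1e-8
    n_null_draws: int = 999
    n_bootstrap: int = 200
    seed: int = 0
    round_cutpoints: bool = True


@dataclass(frozen=True)
class ThresholdDerivation:
    thresholds: Optional[ThresholdSet]
    kde: KdeModes = field(repr=False)
    n_main_modes: int
    note: str = ""

    @property
    def ok(self) -> bool:
        return self.thresholds is not None


def derive_thresholds(x, config: ModalityConfig = ModalityConfig()) -> ThresholdDerivation:
    """Derive level cutpoints as antimodes between substantive KDE modes.

    With ``m`` substantive modes the result has ``m - 1`` cutpoints
    (rounded to the nearest integer percent by default). Unimodal data yield
    an explicit no-thresholds result rather than an error.
    """
    km = kde_modes(
        x,
        bandwidth=config.bandwidth,
        grid_points=config.grid_points,
        min_mode_mass=config.min_mode_mass,
    )
    m = len(km.substantive_modes)
    if m < 2:
        return ThresholdDerivation(
            thresholds=None,
            kde=km,
            n_main_modes=m,
            note="unimodal density: no antimode cutpoints derivable",
        )
    cuts = km.substantive_antimodes
    if config.round_cutpoints:
        cuts = np.round(cuts)
    cuts = tuple(float(c) for c in cuts)
    if len(set(cuts)) != len(cuts):
        return ThresholdDerivation(
            thresholds=None,
            kde=km,
            n_main_modes=m,
            note="degenerate antimodes (coincident after rounding)",
        )
    return ThresholdDerivation(
        thresholds=ThresholdSet(cutpoints=cuts, provenance="derived"),
        kde=km,
        n_main_modes=m,
    )


@dataclass(frozen=True)
class ModalityResult:
    """Bundle of all multimodality evidence for one sample."""

    n: int
    dip: object
    silverman: tuple
    gmm_best_k: int
    gmm_fits: tuple
    derivation: ThresholdDerivation


def modality_analysis(x, config: ModalityConfig = ModalityConfig()) -> ModalityResult:
    """Run the full multimodality battery on one sample.

    Dip test (is the distribution unimodal at all?), Silverman tests for
    k = 1, 2 (how many modes are certain?), Gaussian-mixture BIC scan, and
    KDE-antimode threshold derivation.
    """
    from .gmm import select_k_bic

    xs = np.asarray(x, dtype=float)
    dip_res = dip_test(xs, n_null_draws=config.n_null_draws, seed=config.seed)
    silv = tuple(
        silverman_test(
            xs,
            k=k,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed + k,
            grid_points=config.grid_points,
        )
        for k in (1, 2)
    )
    best_k, fits = select_k_bic(
        xs,
        k_max=config.k_max,
        seed=config.seed,
        n_restarts=config.n_restarts,
        tol=config.em_tol,
    )
    deriv = derive_thresholds(xs, config)
    return ModalityResult(
        n=xs.size,
        dip=dip_res,
        silverman=silv,
        gmm_best_k=best_k,
        gmm_fits=tuple(fits),
        derivation=deriv,
    )


@dataclass(frozen=True)
class LeaveOrderOutResult:
    full: Optional[ThresholdSet]
    reduced: Optional[ThresholdSet]
    shifts: Optional[tuple[float, ...]]
    n_full: int
    n_reduced: int
    stable: Optional[bool]
    note: str = ""


def robustness_leave_order_out(
    values: Sequence[float],
    order_codes: Sequence[str],
    exclude_order: str,
    config: ModalityConfig = ModalityConfig(),
    min_remaining: int = 20,
    stability_bound: float = 5.0,
) -> LeaveOrderOutResult:
    """Compare thresholds derived with and without one taxonomic order.

    Guards against a single heavily sampled order (e.g. Fabales at ~60% of
    species) dictating the category boundaries. ``shifts`` are element-wise
    (reduced - full); ``stable`` flags whether all |shift| stay within
    ``stability_bound`` percentage points.
    """
    from dataclasses import replace

    from .kde import resolve_bandwidth

    vals = np.asarray(values, dtype=float)
    codes = np.asarray(order_codes)
    mask = codes != exclude_order
    n_reduced = int(mask.sum())
    if n_reduced < min_remaining:
        return LeaveOrderOutResult(
            full=None, reduced=None, shifts=None,
            n_full=vals.size, n_reduced=n_reduced, stable=None,
            note=f"only {n_reduced} species remain after excluding {exclude_order}",
        )
    # hold the full-data bandwidth fixed so the comparison isolates the effect
    # of removing the order (not of re-selecting the smoothing)
    h = resolve_bandwidth(vals, config.bandwidth)
    fixed = replace(config, bandwidth=h)
    d_full = derive_thresholds(vals, fixed)
    d_red = derive_thresholds(vals[mask], fixed)
    if not (d_full.ok and d_red.ok) or len(d_full.thresholds.cutpoints) != len(
        d_red.thresholds.cutpoints
    ):
        return LeaveOrderOutResult(
            full=d_full.thresholds, reduced=d_red.thresholds, shifts=None,
            n_full=vals.size, n_reduced=n_reduced, stable=False,
            note="mode structure changed; cutpoints not comparable",
        )
    shifts = tuple(
        float(b - a)
        for a, b in zip(d_full.thresholds.cutpoints, d_red.thresholds.cutpoints)
    )
    return LeaveOrderOutResult(
        full=d_full.thresholds,
        reduced=ThresholdSet(
            cutpoints=d_red.thresholds.cutpoints,
            provenance="derived",
            robustness_shift=shifts,
        ),
        shifts=shifts,
        n_full=vals.size,
        n_reduced=n_reduced,
        stable=bool(max(abs(s) for s in shifts) <= stability_bound),
    )
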