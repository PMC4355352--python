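"""Gating and DNA-content histogram deconvolution.

Raw PI-fluorescence event tables are reduced to the four cell-cycle
phase proportions (sub-G1, G1, S, G2) used for atresia staging:

1. scatter gating removes debris (low FSC/SSC) and a peak-vs-integrated
   fluorescence ratio gate removes doublets;
2. the integrated-fluorescence histogram is decomposed by penalized least
   squares into an exponential sub-G1 smear, a Gaussian G1 peak, a
   broadened-uniform S plateau and a Gaussian G2 peak locked at twice the
   G1 mean;
3. the resulting proportions are normalized to sum to exactly 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

EVENT_COLUMNS = ("fsc", "ssc", "peak_fluor", "integrated_fluor")


class GatingError(ValueError):
    """Raised when gating cannot produce a usable event set."""


class FitError(RuntimeError):
    """Raised when the histogram deconvolution fails to converge."""


@dataclass(frozen=True)
class GateConfig:
    """Scatter and doublet gates.

    ``doublet_ratio_min`` is the minimum peak/integrated fluorescence
    ratio: doublets take longer to transit the laser, inflating the
    integrated signal relative to the peak.
    """

    fsc_min: float = 150.0
    ssc_min: float = 100.0
    doublet_ratio_min: float = 0.6
    target_events: int = 10_000

    def __post_init__(self):
        if self.fsc_min < 0 or self.ssc_min < 0:
            raise ValueError("scatter thresholds must be >= 0")
        if not 0 < self.doublet_ratio_min < 1:
            raise ValueError("doublet_ratio_min must lie in (0, 1)")


@dataclass(frozen=True)
class DnaModelConfig:
    """Controls for the DNA-content mixture fit."""

    n_bins: int = 256
    g2_g1_ratio: float = 2.0
    subG1_boundary_k: float = 3.0
    max_iter: int = 2000
    tol: float = 1e-10

    def __post_init__(self):
        if self.n_bins < 64:
            raise ValueError("n_bins must be >= 64")
        if not 1.8 <= self.g2_g1_ratio <= 2.2:
            raise ValueError("g2_g1_ratio must lie in [1.8, 2.2]")


@dataclass(frozen=True)
class PhaseProfile:
    """Percentages of modeled events per cell-cycle phase."""

    p_subG1: float
    p_G1: float
    p_S: float
    p_G2: float
    normalized: bool = False
    fit_quality: float = float("nan")

    def __post_init__(self):
        for name in ("p_subG1", "p_G1", "p_S", "p_G2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.normalized and abs(self.total - 100.0) > 1e-9:
            raise ValueError(f"normalized profile must sum to 100, got {self.total}")

    @property
    def total(self) -> float:
        return self.p_subG1 + self.p_G1 + self.p_S + self.p_G2

    def as_tuple(self) -> tuple:
        return (self.p_subG1, self.p_G1, self.p_S, self.p_G2)


def gate_events(events: pd.DataFrame, cfg: GateConfig | None = None, seed: int = 0):
    """Apply debris and doublet gates, then subsample to ``target_events``.

    Returns ``(gated table, report)`` where the report is a dict with the
    number of events removed per rule. Raises :class:`GatingError` on an
    empty input or when every event is gated out.
    """
    cfg = cfg or GateConfig()
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise GatingError(f"event table is missing columns: {missing}")
    if len(events) == 0:
        raise GatingError("event table is empty")

    n_in = len(events)
    debris_mask = (events["fsc"] < cfg.fsc_min) | (events["ssc"] < cfg.ssc_min)
    kept = events.loc[~debris_mask]
    ratio = kept["peak_fluor"] / kept["integrated_fluor"]
    doublet_mask = ratio < cfg.doublet_ratio_min
    kept = kept.loc[~doublet_mask]

    report = {
        "n_input": n_in,
        "removed_debris": int(debris_mask.sum()),
        "removed_doublets": int(doublet_mask.sum()),
        "removed_subsample": 0,
        "n_retained": len(kept),
    }
    if len(kept) == 0:
        raise GatingError(f"all events gated out: {report}")
    if len(kept) > cfg.target_events:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(kept), size=cfg.target_events, replace=False)
        idx.sort()
        report["removed_subsample"] = len(kept) - cfg.target_events
        kept = kept.iloc[idx]
        report["n_retained"] = len(kept)
    return kept.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# histogram deconvolution
# ---------------------------------------------------------------------------


def _component_shapes(x: np.ndarray, mu: float, sigma: float, tau: float, cfg: DnaModelConfig):
    """Densities of the four phase components evaluated at bin centers.

    Each returned column integrates to ~1 over the axis, so fitted weights
    are event fractions directly.
    """
    g1 = stats.norm.pdf(x, mu, sigma)
    g2_mu = cfg.g2_g1_ratio * mu
    g2 = stats.norm.pdf(x, g2_mu, cfg.g2_g1_ratio * sigma)
    # S phase: uniform on (mu, g2_mu) convolved with the G1 Gaussian
    span = g2_mu - mu
    s = (stats.norm.cdf((x - mu) / sigma) - stats.norm.cdf((x - g2_mu) / sigma)) / span
    # sub-G1: exponential decay below the boundary, truncated at zero
    b = mu - cfg.subG1_boundary_k * sigma
    norm = tau * (1.0 - math.exp(-b / tau))
    sub = np.where(x <= b, np.exp(-(b - x) / tau) / norm, 0.0)
    return np.column_stack([sub, g1, s, g2])


def fit_dna_histogram(gated: pd.DataFrame, cfg: DnaModelConfig | None = None) -> PhaseProfile:
    """Decompose the integrated-fluorescence histogram into phase fractions.

    The G1 mean, common CV and sub-G1 decay scale are optimized jointly
    with the four component weights by bounded least squares on the binned
    counts. Returns a raw (un-normalized) :class:`PhaseProfile`; the
    residual RMS relative to the modal bin count is stored as
    ``fit_quality``.
    """
    cfg = cfg or DnaModelConfig()
    values = np.asarray(gated["integrated_fluor"], dtype=float)
    if len(values) < 500:
        raise ValueError(f"need >= 500 gated events to fit, got {len(values)}")

    counts, edges = np.histogram(values, bins=cfg.n_bins, range=(0.0, values.max() * 1.02))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    total = counts.sum()

    # initial G1 estimate: modal bin (smoothed) — G1 dominates every stage
    smooth = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    mu0 = float(centers[np.argmax(smooth)])
    sigma0 = 0.05 * mu0
    tau0 = 0.3 * max(mu0 - cfg.subG1_boundary_k * sigma0, 1.0)

    def weights_for(shape_params):
        mu, sigma, tau = shape_params
        X = _component_shapes(centers, mu, sigma, tau, cfg) * total * width
        w, _ = optimize.nnls(X, counts.astype(float))
        return w, X

    def residual(shape_params):
        w, X = weights_for(shape_params)
        return X @ w - counts

    lower = [0.6 * mu0, 0.01 * mu0, 1e-3]
    upper = [1.4 * mu0, 0.15 * mu0, mu0]
    try:
        res = optimize.least_squares(
            residual,
            x0=[mu0, sigma0, tau0],
            bounds=(lower, upper),
            max_nfev=cfg.max_iter,
            xtol=cfg.tol,
            ftol=cfg.tol,
        )
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise FitError(f"histogram fit failed: {exc}") from exc
    if not res.success and res.status == 0:
        raise FitError(
            f"histogram fit did not converge in {cfg.max_iter} evaluations; last residual norm {np.linalg.norm(res.fun):.3g}"
        )

    w, _ = weights_for(res.x)
    fractions = 100.0 * w / max(w.sum(), 1e-300)
    rms = float(np.sqrt(np.mean(res.fun**2)) / max(counts.max(), 1))
    return PhaseProfile(
        p_subG1=float(fractions[0]),
        p_G1=float(fractions[1]),
        p_S=float(fractions[2]),
        p_G2=float(fractions[3]),
        normalized=False,
        fit_quality=rms,
    )


def round_profile(profile: PhaseProfile, decimals: int = 2) -> PhaseProfile:
    """Round each proportion independently (emulated reporting mode).

    Independent rounding makes the reported sum drift away from 100, the
    behaviour normalization is designed to repair. Off by default in the
    pipeline.
    """
    return replace(
        profile,
        p_subG1=round(profile.p_subG1, decimals),
        p_G1=round(profile.p_G1, decimals),
        p_S=round(profile.p_S, decimals),
        p_G2=round(profile.p_G2, decimals),
        normalized=False,
    )


def normalize_proportions(profile: PhaseProfile) -> PhaseProfile:
    """Rescale phase proportions to sum to exactly 100.

    Each phase value is divided by the sum of all four and multiplied by
    100. Raises ``ValueError`` on an all-zero profile.
    """
    total = profile.total
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    scaled = [100.0 * v / total for v in profile.as_tuple()]
    # absorb the floating-point drift into one component so the reported
    # sum is exactly 100; rounding can skip the target for a given slot,
    # so try components from largest down until the sum lands exactly
    vals = list(scaled)
    for slot in np.argsort(scaled)[::-1]:
        vals = list(scaled)
        for _ in range(6):
            drift = 100.0 - (vals[0] + vals[1] + vals[2] + vals[3])
            if drift == 0.0:
                break
            vals[int(slot)] += drift
        if vals[0] + vals[1] + vals[2] + vals[3] == 100.0:
            break
    return replace(
        profile,
        p_subG1=vals[0],
        p_G1=vals[1],
        p_S=vals[2],
        p_G2=vals[3],
        normalized=True,
    )
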