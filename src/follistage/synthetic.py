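"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the three data modalities the pipeline consumes:

* PI-stained DNA-content flow-cytometry events per follicle, with tunable
  sub-G1 / G1 / S / G2 fractions plus debris and doublet contamination;
* two-color loop-design microarrays (growing-plateau, plateau-atretic,
  growing-atretic contrasts with dye-swap technical replicate slides);
* qPCR Cq tables derived from a log-linear amplification model, with
  five-point decade dilution series and two stage-stable reference genes.

Every generator is a pure function of its configuration and an integer
seed, so downstream recovery can be scored against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("growing", "plateau", "atretic")
CONTRASTS = ("G_vs_P", "P_vs_A", "G_vs_A")

#: which stages each contrast compares, in (first, second) order; a positive
#: effect means up-regulation in the second item.
CONTRAST_STAGES = {
    "G_vs_P": ("growing", "plateau"),
    "P_vs_A": ("plateau", "atretic"),
    "G_vs_A": ("growing", "atretic"),
}

# Default phase mixes per stage (percent sub-G1, G1, S, G2). Atresia is
# marked by apoptotic DNA loss (high sub-G1) and loss of cycling cells.
DEFAULT_STAGE_PHASES = {
    "growing": (2.0, 78.0, 12.0, 8.0),
    "plateau": (10.0, 80.0, 6.0, 4.0),
    "atretic": (30.0, 62.0, 4.0, 4.0),
}

PHASE_FIELDS = ("p_subG1", "p_G1", "p_S", "p_G2")
TRUTH_CLASSES = ("subG1", "G1", "S", "G2", "debris", "doublet")


class ValidationError(ValueError):
    """Raised when a generator configuration violates its preconditions."""


@dataclass(frozen=True)
class StageTruth:
    """Ground-truth description of one follicle stage.

    Percentages refer to the singlet cell population (before debris or
    doublet contamination is added) and must sum to 100.
    """

    stage: str
    p_subG1: float
    p_G1: float
    p_S: float
    p_G2: float
    de_genes: dict = field(default_factory=dict)
    marker_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")
        for name in PHASE_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be a non-negative finite percent, got {v}")
        total = self.p_subG1 + self.p_G1 + self.p_S + self.p_G2
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(f"phase percentages must sum to 100, got {total}")
        for g, e in self.de_genes.items():
            if not math.isfinite(e):
                raise ValidationError(f"effect for {g} is not finite")

    @property
    def phases(self) -> tuple:
        return (self.p_subG1, self.p_G1, self.p_S, self.p_G2)

    @classmethod
    def for_stage(cls, stage: str, **kw) -> "StageTruth":
        p = DEFAULT_STAGE_PHASES[stage]
        return cls(stage=stage, p_subG1=p[0], p_G1=p[1], p_S=p[2], p_G2=p[3], **kw)


@dataclass(frozen=True)
class NoiseConfig:
    """Instrument / preparation noise for the event generator.

    g1_mean_channel: G1 peak location on the 1024-channel integrated
    fluorescence axis; G2 sits at exactly twice this (PI linearity).
    g1_cv: coefficient of variation of the G1 and G2 Gaussians.
    subg1_decay_frac: scale of the exponential DNA-loss smear below the
    G1 peak, as a fraction of the sub-G1 boundary position.
    """

    g1_mean_channel: float = 200.0
    g1_cv: float = 0.04
    subg1_boundary_k: float = 3.0
    subg1_decay_frac: float = 0.35
    debris_frac: float = 0.0
    doublet_frac: float = 0.0
    fsc_mean: float = 400.0
    fsc_cv: float = 0.20
    ssc_mean: float = 300.0
    ssc_cv: float = 0.25
    debris_scatter_frac: float = 0.15
    peak_jitter_cv: float = 0.02

    def __post_init__(self):
        if not 0 <= self.debris_frac < 1 or not 0 <= self.doublet_frac < 1:
            raise ValidationError("debris_frac and doublet_frac must lie in [0, 1)")
        if self.debris_frac + self.doublet_frac >= 1:
            raise ValidationError("debris_frac + doublet_frac must be < 1")
        if self.g1_cv <= 0 or self.g1_mean_channel <= 0:
            raise ValidationError("g1_mean_channel and g1_cv must be positive")


def _singlet_fluorescence(cls_name: str, n: int, noise: NoiseConfig, rng: np.random.Generator):
    """Integrated fluorescence for ``n`` singlet events of one cell-cycle class."""
    mu = noise.g1_mean_channel
    sigma = mu * noise.g1_cv
    if cls_name == "G1":
        x = rng.normal(mu, sigma, n)
    elif cls_name == "G2":
        x = rng.normal(2 * mu, 2 * mu * noise.g1_cv, n)
    elif cls_name == "S":
        # uniform DNA content between G1 and G2 means, convolved with the
        # G1 spread (pragmatic broadened-plateau S model)
        x = rng.uniform(mu, 2 * mu, n) + rng.normal(0.0, sigma, n)
    elif cls_name == "subG1":
        # left-truncated exponential decay below the G1 peak region:
        # fragmented-DNA events pile up just under the boundary and thin
        # out toward zero
        boundary = mu - noise.subg1_boundary_k * sigma
        tau = noise.subg1_decay_frac * boundary
        x = boundary - rng.exponential(tau, n)
        bad = x <= 0
        while bad.any():
            x[bad] = boundary - rng.exponential(tau, int(bad.sum()))
            bad = x <= 0
    else:  # pragma: no cover - guarded by caller
        raise ValueError(cls_name)
    return np.clip(x, 1e-6, None)


def simulate_follicle_events(
    truth: StageTruth,
    n_events: int = 10_000,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate PI-stained DNA-content events for one follicle.

    Returns a table with columns ``fsc``, ``ssc``, ``peak_fluor``,
    ``integrated_fluor`` and the generator-only ``truth_class``.
    ``n_events`` singlet cells are drawn multinomially from the truth
    percentages; debris and doublet events are added on top at the
    configured fractions, so gating can be scored against truth labels.
    """
    if n_events < 100:
        raise ValidationError(f"n_events must be >= 100, got {n_events}")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)

    probs = np.asarray(truth.phases, dtype=float) / 100.0
    counts = rng.multinomial(n_events, probs)
    classes = ("subG1", "G1", "S", "G2")

    frames = []
    for cls_name, n in zip(classes, counts):
        if n == 0:
            continue
        integ = _singlet_fluorescence(cls_name, int(n), noise, rng)
        # peak fluorescence tracks integrated fluorescence for singlets
        # (up to jitter): single particles transit the laser quickly
        peak = integ * rng.normal(1.0, noise.peak_jitter_cv, int(n))
        fsc = rng.normal(noise.fsc_mean, noise.fsc_mean * noise.fsc_cv, int(n))
        ssc = rng.normal(noise.ssc_mean, noise.ssc_mean * noise.ssc_cv, int(n))
        frames.append(
            pd.DataFrame(
                {
                    "fsc": np.clip(fsc, 1e-6, None),
                    "ssc": np.clip(ssc, 1e-6, None),
                    "peak_fluor": np.clip(peak, 1e-6, None),
                    "integrated_fluor": integ,
                    "truth_class": cls_name,
                }
            )
        )
    singlets = pd.concat(frames, ignore_index=True)

    extras = []
    n_debris = rng.binomial(n_events, noise.debris_frac) if noise.debris_frac else 0
    if n_debris:
        frac = noise.debris_scatter_frac
        integ = rng.exponential(0.15 * noise.g1_mean_channel, n_debris) + 1e-6
        extras.append(
            pd.DataFrame(
                {
                    "fsc": np.clip(rng.normal(noise.fsc_mean * frac, noise.fsc_mean * frac * 0.4, n_debris), 1e-6, None),
                    "ssc": np.clip(rng.normal(noise.ssc_mean * frac, noise.ssc_mean * frac * 0.4, n_debris), 1e-6, None),
                    "peak_fluor": integ * rng.normal(1.0, noise.peak_jitter_cv, n_debris),
                    "integrated_fluor": integ,
                    "truth_class": "debris",
                }
            )
        )
    n_doublet = rng.binomial(n_events, noise.doublet_frac) if noise.doublet_frac else 0
    if n_doublet:
        # a doublet is two cells transiting together: integrated signal is
        # the sum of the pair, peak signal only the larger of the two
        i = rng.integers(0, len(singlets), n_doublet)
        j = rng.integers(0, len(singlets), n_doublet)
        a = singlets["integrated_fluor"].to_numpy()
        pk = singlets["peak_fluor"].to_numpy()
        extras.append(
            pd.DataFrame(
                {
                    "fsc": rng.normal(noise.fsc_mean * 1.5, noise.fsc_mean * noise.fsc_cv, n_doublet).clip(1e-6),
                    "ssc": rng.normal(noise.ssc_mean * 1.5, noise.ssc_mean * noise.ssc_cv, n_doublet).clip(1e-6),
                    "peak_fluor": np.maximum(pk[i], pk[j]),
                    "integrated_fluor": a[i] + a[j],
                    "truth_class": "doublet",
                }
            )
        )

    table = pd.concat([singlets, *extras], ignore_index=True)
    # shuffle so acquisition order carries no class information
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)


@dataclass(frozen=True)
class FollicleTruth:
    """Hidden truth for one simulated follicle."""

    sample_id: str
    stage: str
    diameter_mm: float
    rin: float
    truth: StageTruth


def simulate_cohort(
    n_follicles: int = 27,
    stage_mix: dict | None = None,
    diameter_range_mm: tuple = (9.5, 20.0),
    rin_range: tuple = (7.0, 9.3),
    n_low_rin: int = 0,
    low_rin_value: float = 5.0,
    n_events: int = 10_000,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> list:
    """Simulate a slaughterhouse cohort of dominant follicles (>9 mm).

    Returns a list of ``(FollicleTruth, event table)`` pairs. ``stage_mix``
    maps stage name to follicle count (defaults to a near-even split).
    ``n_low_rin`` follicles (chosen at random) receive a degraded RIN so
    QC exclusion paths can be exercised.
    """
    if diameter_range_mm[0] <= 9.0:
        raise ValidationError(
            f"diameter_range_mm lower bound must exceed 9 mm (dominant follicles), got {diameter_range_mm[0]}"
        )
    if n_follicles == 0:
        return []
    if stage_mix is None:
        base = n_follicles // 3
        stage_mix = {
            "growing": base + (n_follicles % 3 > 0),
            "plateau": base + (n_follicles % 3 > 1),
            "atretic": base,
        }
    if sum(stage_mix.values()) != n_follicles:
        raise ValidationError("stage_mix counts must sum to n_follicles")
    if n_low_rin > n_follicles:
        raise ValidationError("n_low_rin cannot exceed n_follicles")

    rng = np.random.default_rng(seed)
    stages = [s for s, k in stage_mix.items() for _ in range(k)]
    rng.shuffle(stages)
    low_idx = set(rng.choice(n_follicles, size=n_low_rin, replace=False).tolist())

    cohort = []
    for i, stage in enumerate(stages):
        truth = StageTruth.for_stage(stage)
        diameter = float(rng.uniform(*diameter_range_mm))
        rin = low_rin_value if i in low_idx else float(rng.uniform(*rin_range))
        sample_id = f"F{i + 1:02d}"
        events = simulate_follicle_events(
            truth, n_events=n_events, noise=noise, seed=int(rng.integers(0, 2**31 - 1))
        )
        cohort.append(
            (FollicleTruth(sample_id=sample_id, stage=stage, diameter_mm=diameter, rin=rin, truth=truth), events)
        )
    return cohort


# ---------------------------------------------------------------------------
# two-color loop-design arrays
# ---------------------------------------------------------------------------


def simulate_loop_arrays(
    stage_assignment: dict,
    n_probes: int = 2000,
    de_config: dict | None = None,
    dye_bias: float = 0.3,
    n_replicates: int = 4,
    dye_swap: bool = True,
    base_mean: float = 9.0,
    base_sd: float = 1.5,
    noise_sd: float = 0.25,
    bio_sd: float = 0.15,
    background_level: float = 30.0,
    seed: int = 0,
):
    """Simulate a dye-swap loop design over the three stage contrasts.

    ``stage_assignment`` maps sample id to stage and must cover all three
    stages with at least ``n_replicates`` samples each. ``de_config`` maps
    contrast name to ``{probe_id: signed log2 effect}`` where a positive
    effect means up-regulation in the second item of the contrast.
    Each contrast gets ``n_replicates`` biological sample pairs, each
    hybridized on two slides with dyes exchanged (when ``dye_swap``).

    Returns a :class:`~follistage.microarray.TwoColorArraySet`.
    """
    from follistage.microarray import TwoColorArraySet

    if n_probes < 1:
        raise ValidationError(f"n_probes must be >= 1, got {n_probes}")
    by_stage = {s: [k for k, v in stage_assignment.items() if v == s] for s in STAGES}
    for s, members in by_stage.items():
        if len(members) < n_replicates:
            raise ValidationError(
                f"stage_assignment must provide >= {n_replicates} samples for stage {s!r}, got {len(members)}"
            )
    de_config = de_config or {}
    rng = np.random.default_rng(seed)

    probes = np.array([f"P{i + 1:05d}" for i in range(n_probes)])
    base = rng.normal(base_mean, base_sd, n_probes)  # log2 scale

    # per-stage true expression: effects are applied as transition effects
    # so each configured contrast is realized exactly — a G_vs_P effect
    # shifts plateau and atretic alike (a change at the G->P transition
    # persists), a P_vs_A or G_vs_A effect shifts atretic only; the loop
    # constraint makes G_vs_A truth the sum of the two transitions
    stage_expr = {s: base.copy() for s in STAGES}
    probe_index = {p: i for i, p in enumerate(probes)}
    for contrast, effects in de_config.items():
        if contrast not in CONTRASTS:
            raise ValidationError(f"unknown contrast {contrast!r} in de_config")
        for probe, eff in effects.items():
            idx = probe_index[probe]
            if contrast == "G_vs_P":
                stage_expr["plateau"][idx] += eff
                stage_expr["atretic"][idx] += eff
            else:  # P_vs_A or G_vs_A: a change appearing at atresia
                stage_expr["atretic"][idx] += eff
    truth_effects = {}
    for contrast in CONTRASTS:
        first, second = CONTRAST_STAGES[contrast]
        truth_effects[contrast] = stage_expr[second] - stage_expr[first]

    # per-hybridization expression: stage truth + biological/preparation
    # wobble redrawn per channel (each labeling starts from a fresh RNA
    # aliquot, so slides are conditionally independent given the stage)
    stage_of_sample = dict(stage_assignment)
    chan_sd = math.hypot(bio_sd, noise_sd)

    rows = []
    arrays = []
    for contrast in CONTRASTS:
        first, second = CONTRAST_STAGES[contrast]
        for r in range(n_replicates):
            s_first = by_stage[first][r]
            s_second = by_stage[second][r]
            orientations = [(s_first, s_second)]
            if dye_swap:
                orientations.append((s_second, s_first))
            pair_ids = []
            for o, (green_sample, red_sample) in enumerate(orientations):
                array_id = f"{contrast}_r{r + 1}_{'fwd' if o == 0 else 'swp'}"
                pair_ids.append(array_id)
                for channel, sample in (("green", green_sample), ("red", red_sample)):
                    log2_sig = stage_expr[stage_of_sample[sample]] + rng.normal(0.0, chan_sd, n_probes)
                    if channel == "red":
                        log2_sig = log2_sig + dye_bias  # gene-independent dye bias
                    fg = 2.0**log2_sig + background_level
                    bg = np.full(n_probes, background_level) + rng.normal(0.0, 1.0, n_probes)
                    rows.append(
                        pd.DataFrame(
                            {
                                "array_id": array_id,
                                "contrast": contrast,
                                "dye": channel,
                                "sample_id": sample,
                                "probe_id": probes,
                                "fg": fg,
                                "bg": np.clip(bg, 0.0, None),
                            }
                        )
                    )
            arrays.append(
                {
                    "contrast": contrast,
                    "replicate": r + 1,
                    "array_ids": pair_ids,
                    "samples": {"fwd": (s_first, s_second)},
                }
            )

    long = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({"probe_id": probes, **{c: truth_effects[c] for c in CONTRASTS}})
    return TwoColorArraySet.from_long(long, truth=truth)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

REFERENCE_GENES = ("EIF2B2", "SF3A1")
DEFAULT_DILUTION_NG = (1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


def simulate_qpcr(
    stage_assignment: dict,
    genes: list,
    curve_params: dict | None = None,
    marker_levels: dict | None = None,
    dilution_ng: tuple = DEFAULT_DILUTION_NG,
    noise_sd: float = 0.15,
    bio_cv: float = 0.25,
    contaminated_sample: str | None = None,
    contamination_gene: str = "CYP17A1",
    contamination_fold: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate Cq tables plus dilution-series standards.

    ``marker_levels`` maps gene -> {stage: mean quantity ng}; genes absent
    from it (and the two reference genes) are stage-independent. The
    returned long table has columns ``gene, sample, stage, Cq,
    is_standard, input_ng`` — standards carry their known input quantity.
    ``contaminated_sample`` optionally marks one sample with an elevated
    ``contamination_gene`` level (theca-cell contamination analogue).
    """
    q = np.asarray(dilution_ng, dtype=float)
    if len(q) < 2 or not (np.diff(q) < 0).all():
        raise ValidationError("dilution series must be strictly decreasing in quantity")
    rng = np.random.default_rng(seed)
    curve_params = curve_params or {}
    marker_levels = marker_levels or {}
    all_genes = list(dict.fromkeys(list(genes) + list(REFERENCE_GENES)))

    rows = []
    for gene in all_genes:
        slope, intercept = curve_params.get(gene, (-3.4, 18.0))
        if slope >= 0:
            raise ValidationError(f"standard-curve slope for {gene} must be negative")
        # dilution standards
        for qty in q:
            cq = intercept + slope * math.log10(qty) + rng.normal(0.0, noise_sd)
            rows.append((gene, f"std_{qty:.0e}", "", cq, True, qty))
        # unknowns
        base_qty = 5e-6 if gene in REFERENCE_GENES else 2e-6
        for sample, stage in stage_assignment.items():
            level = marker_levels.get(gene, {}).get(stage, base_qty)
            qty = level * float(rng.lognormal(0.0, bio_cv))
            if contaminated_sample == sample and gene == contamination_gene:
                qty *= contamination_fold
            cq = intercept + slope * math.log10(qty) + rng.normal(0.0, noise_sd)
            rows.append((gene, sample, stage, cq, False, math.nan))
    return pd.DataFrame(rows, columns=["gene", "sample", "stage", "Cq", "is_standard", "input_ng"])
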