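"""qPCR quantification and stage-validation statistics.

Cq values are converted to input quantities through five-point decade
standard curves (Cq = intercept + slope * log10(ng)), normalized by the
geometric mean of two stable reference transcripts (EIF2B2, SF3A1 by
default), screened for theca-cell contamination via Bartlett's
equal-variance test with leave-one-out attribution, and compared across
the three follicle stages with one-tailed t tests, one-way ANOVA with a
Newman-Keuls post hoc, a linear-trend post-test, and a variance-
stabilizing log transform (Y = log10(y * 1e12)) applied when Bartlett's
test rejects homogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_GENES = ("EIF2B2", "SF3A1")
STAGE_ORDER = ("growing", "plateau", "atretic")
CONTRASTS = (("growing", "plateau"), ("plateau", "atretic"), ("growing", "atretic"))


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear calibration of one assay."""

    gene: str
    slope: float
    intercept: float
    r2: float
    n_points: int

    @property
    def efficiency(self) -> float:
        """Amplification efficiency: 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(records: pd.DataFrame, gene: str | None = None) -> StandardCurve:
    """Least-squares fit of Cq against log10(input ng) for one gene.

    ``records`` needs columns ``Cq`` and ``input_ng`` (optionally ``gene``
    to subset). Requires >= 3 strictly monotone quantities; a positive
    fitted slope is rejected as miswired input (more template must amplify
    earlier).
    """
    df = records
    if gene is not None and "gene" in df.columns:
        df = df[df["gene"] == gene]
    df = df.dropna(subset=["Cq", "input_ng"])
    if len(df) < 3:
        raise QpcrError(f"standard curve needs >= 3 points, got {len(df)}")
    q = df["input_ng"].to_numpy(dtype=float)
    if len(np.unique(q)) != len(q):
        raise QpcrError("dilution quantities must be distinct")
    fit = stats.linregress(np.log10(q), df["Cq"].to_numpy(dtype=float))
    if fit.slope >= 0:
        raise QpcrError(f"positive standard-curve slope ({fit.slope:.3f}): inputs look miswired")
    return StandardCurve(
        gene=gene or (df["gene"].iloc[0] if "gene" in df.columns else ""),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_points=len(df),
    )


def quantify(cq, curve: StandardCurve):
    """Invert the standard curve: quantity = 10 ** ((Cq - intercept) / slope).

    Absent Cq values (NaN) propagate to absent quantities.
    """
    cq = np.asarray(cq, dtype=float)
    out = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return out if out.ndim else float(out)


@dataclass
class QpcrPanel:
    """Quantities per gene x sample, plus normalization bookkeeping.

    ``quantities`` is a genes x samples frame of ng inputs; undetected
    transcripts are NaN (never silently zero). ``stages`` maps sample to
    stage. After :func:`genorm_normalize`, ``normalized`` holds the
    reference-scaled quantities and ``norm_factors`` the per-sample
    geometric means.
    """

    quantities: pd.DataFrame
    stages: dict
    reference_genes: tuple = REFERENCE_GENES
    curves: dict = field(default_factory=dict)
    normalized: pd.DataFrame | None = None
    norm_factors: pd.Series | None = None
    stability_m: dict | None = None

    @classmethod
    def from_cq_table(cls, table: pd.DataFrame, reference_genes: tuple = REFERENCE_GENES) -> "QpcrPanel":
        """Build a panel from a long Cq table with dilution standards.

        Standards (``is_standard`` truthy) calibrate each gene's curve;
        unknowns are quantified through it.
        """
        std = table[table["is_standard"].astype(bool)]
        unk = table[~table["is_standard"].astype(bool)]
        curves = {g: fit_standard_curve(grp, gene=g) for g, grp in std.groupby("gene")}
        missing = sorted(set(unk["gene"]) - set(curves))
        if missing:
            raise QpcrError(f"no dilution series for genes: {missing}")
        rows = unk.copy()
        rows["quantity"] = [
            quantify(cq, curves[g]) if np.isfinite(cq) else np.nan
            for g, cq in zip(rows["gene"], rows["Cq"])
        ]
        quantities = rows.pivot_table(index="gene", columns="sample", values="quantity", dropna=False)
        stages = dict(zip(unk["sample"], unk["stage"])) if "stage" in unk.columns else {}
        return cls(quantities=quantities, stages=stages, reference_genes=reference_genes, curves=curves)


def genorm_normalize(panel: QpcrPanel) -> QpcrPanel:
    """Divide each quantity by its sample's reference geometric mean.

    The normalization factor of a sample is the geometric mean of its
    reference-gene quantities; target quantities are divided by it. The
    reference-gene stability measure M (mean standard deviation of
    pairwise log2 ratios against the other references) is reported for
    audit. A reference gene missing in any sample is an error naming the
    sample.
    """
    q = panel.quantities
    for ref in panel.reference_genes:
        if ref not in q.index:
            raise QpcrError(f"reference gene {ref} absent from the panel")
        bad = q.columns[q.loc[ref].isna()].tolist()
        if bad:
            raise QpcrError(f"reference gene {ref} not quantified in sample(s) {bad}")
    refs = q.loc[list(panel.reference_genes)]
    factors = np.exp(np.log(refs).mean(axis=0))  # per-sample geometric mean
    normalized = q.drop(index=list(panel.reference_genes)) / factors

    m = {}
    for ref in panel.reference_genes:
        sds = []
        for other in panel.reference_genes:
            if other == ref:
                continue
            ratio = np.log2(q.loc[ref] / q.loc[other])
            sds.append(float(ratio.std(ddof=1)))
        m[ref] = float(np.mean(sds))
    panel.normalized = normalized
    panel.norm_factors = factors
    panel.stability_m = m
    return panel


# ---------------------------------------------------------------------------
# contamination QC
# ---------------------------------------------------------------------------


def contamination_qc(
    panel: QpcrPanel,
    marker_gene: str,
    group_labels: dict | None = None,
    fold_threshold: float = 5.0,
    alpha: float = 0.05,
):
    """Flag samples whose marker level breaks variance homogeneity.

    Bartlett's test is run on the marker quantity across groups; when it
    rejects at ``alpha``, each sample is tested by leave-one-out — a
    sample is flagged when removing it renders Bartlett non-significant
    AND its marker level exceeds its group median by ``fold_threshold``.
    Returns ``(flagged sample list, report dict)``.
    """
    labels = group_labels or panel.stages
    source = panel.quantities if marker_gene in panel.quantities.index else panel.normalized
    if source is None or marker_gene not in source.index:
        raise QpcrError(f"marker gene {marker_gene} not quantified")
    values = source.loc[marker_gene].dropna()
    groups = {}
    for s, v in values.items():
        groups.setdefault(labels[s], []).append((s, float(v)))
    if len(groups) < 2:
        raise QpcrError("contamination QC needs >= 2 groups")
    small = [g for g, mem in groups.items() if len(mem) < 2]
    if small:
        raise QpcrError(f"groups of size < 2: {small}")

    def bartlett_p(exclude=None):
        arrays = []
        for mem in groups.values():
            vals = [v for s, v in mem if s != exclude]
            if len(vals) < 2:
                return None
            arrays.append(vals)
        if all(np.ptp(a) == 0 for a in arrays):
            return 1.0  # degenerate constant groups: nothing to test
        return float(stats.bartlett(*arrays).pvalue)

    p0 = bartlett_p()
    report = {"bartlett_p": p0, "leave_one_out": {}}
    flagged = []
    if p0 is not None and p0 < alpha:
        for g, mem in groups.items():
            med = float(np.median([v for _, v in mem]))
            for s, v in mem:
                p_loo = bartlett_p(exclude=s)
                report["leave_one_out"][s] = p_loo
                if p_loo is not None and p_loo >= alpha and med > 0 and v > fold_threshold * med:
                    flagged.append(s)
    return flagged, report


# ---------------------------------------------------------------------------
# stage statistics
# ---------------------------------------------------------------------------


def log_transform(y):
    """Variance-stabilizing transform Y = log10(y * 1e12).

    The large factor keeps typical ng-scale quantities above one so the
    transformed values stay positive.
    """
    return np.log10(np.asarray(y, dtype=float) * 1e12)


@dataclass
class GeneStats:
    gene: str
    n_per_stage: dict
    detected_per_stage: dict
    bartlett_p: float | None
    bartlett_p_after: float | None
    transform_applied: bool
    t_one_tailed: dict  # contrast -> p
    anova_p: float | None
    letters: dict  # stage -> letter group
    trend_p: float | None
    testable: bool
    note: str = ""


@dataclass
class StatsReport:
    genes: dict  # gene -> GeneStats

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, st in self.genes.items():
            row = {
                "gene": g,
                "bartlett_p": st.bartlett_p,
                "bartlett_p_after": st.bartlett_p_after,
                "transform_applied": st.transform_applied,
                "anova_p": st.anova_p,
                "trend_p": st.trend_p,
                "testable": st.testable,
            }
            for (a, b), p in st.t_one_tailed.items():
                row[f"t_{a[0].upper()}_vs_{b[0].upper()}"] = p
            for stage, letter in st.letters.items():
                row[f"letter_{stage}"] = letter
            rows.append(row)
        return pd.DataFrame(rows)


def newman_keuls(groups: dict, alpha: float = 0.05):
    """Stepwise Newman-Keuls comparison of group means.

    ``groups`` maps name to 1-D sample array. Means are ordered; pairs
    spanning r ordered means are compared against the studentized-range
    critical value at span r, with the usual blocking rule (a
    non-significant span protects all nested spans). Unequal group sizes
    use the harmonic mean n. Returns ``(significant-pair set, letters)``
    where letters map each group to its homogeneity letters (groups
    sharing a letter are not significantly different).
    """
    names = list(groups)
    data = {g: np.asarray(groups[g], dtype=float) for g in names}
    means = {g: data[g].mean() for g in names}
    ns = {g: len(data[g]) for g in names}
    k = len(names)
    df_within = sum(ns[g] - 1 for g in names)
    if df_within < 1:
        raise QpcrError("Newman-Keuls needs within-group degrees of freedom")
    ms_within = sum(((data[g] - means[g]) ** 2).sum() for g in names) / df_within
    ordered = sorted(names, key=lambda g: means[g])

    significant = set()
    nonsig_spans = []
    if ms_within > 0:
        # examine spans from widest to narrowest so blocking applies
        for span in range(k, 1, -1):
            qcrit = stats.studentized_range.ppf(1 - alpha, span, df_within)
            for start in range(0, k - span + 1):
                lo, hi = ordered[start], ordered[start + span - 1]
                if any(s <= start and e >= start + span - 1 for s, e in nonsig_spans):
                    nonsig_spans.append((start, start + span - 1))
                    continue
                n_h = 2.0 / (1.0 / ns[lo] + 1.0 / ns[hi])
                qval = abs(means[hi] - means[lo]) / math.sqrt(ms_within / n_h)
                if qval > qcrit:
                    significant.add(frozenset((lo, hi)))
                else:
                    nonsig_spans.append((start, start + span - 1))

    # letters: maximal contiguous runs of mutual non-significance over the
    # ordered means (the stepwise procedure yields interval structure)
    runs = []
    for start in range(k):
        end = start
        while end + 1 < k and not any(
            frozenset((ordered[i], ordered[j])) in significant
            for i in range(start, end + 2)
            for j in range(i + 1, end + 2)
        ):
            end += 1
        runs.append((start, end))
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and o[1] >= r[1] for o in runs)]
    letters = {g: "" for g in names}
    for idx, (s, e) in enumerate(sorted(set(maximal))):
        letter = chr(ord("a") + idx)
        for g in ordered[s : e + 1]:
            letters[g] += letter
    return significant, letters


def linear_trend_test(groups_in_order: list):
    """Post-test for linear trend across ordered groups.

    Uses equally spaced contrast coefficients centered at zero on the
    group means; the contrast sum of squares is tested on 1 and
    within-group degrees of freedom. Returns ``(slope_contrast, p)``.
    """
    arrays = [np.asarray(a, dtype=float) for a in groups_in_order]
    k = len(arrays)
    if k < 3:
        raise QpcrError("linear trend needs >= 3 ordered groups")
    coef = np.arange(k, dtype=float) - (k - 1) / 2.0
    means = np.array([a.mean() for a in arrays])
    ns = np.array([len(a) for a in arrays], dtype=float)
    df_within = int(ns.sum()) - k
    ms_within = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within
    L = float((coef * means).sum())
    if ms_within == 0:
        return L, (1.0 if L == 0 else 0.0)
    ss_trend = L**2 / float((coef**2 / ns).sum())
    f = ss_trend / ms_within
    return L, float(stats.f.sf(f, 1, df_within))


def stage_stats(
    panel: QpcrPanel,
    stages: dict | None = None,
    expected_direction: dict | None = None,
    alpha_bartlett: float = 0.05,
    alpha: float = 0.05,
    min_detected: int = 2,
) -> StatsReport:
    """Run the per-gene stage-comparison battery on normalized quantities.

    Per gene: Bartlett's test first; if it rejects at ``alpha_bartlett``
    the quantities are transformed with :func:`log_transform` and Bartlett
    is re-run. Then one-tailed t tests per contrast (direction from
    ``expected_direction``: gene -> contrast -> +1/-1, e.g. the microarray
    fold-change sign; two-tailed halved in the matching direction), a
    one-way ANOVA, a Newman-Keuls letter assignment at ``alpha``, and a
    linear-trend post-test over growing -> plateau -> atretic. Undetected
    values are excluded pairwise (detection counts are reported, nothing
    is imputed); genes without ``min_detected`` detected values in >= 2
    stages are reported untestable rather than raising.
    """
    if panel.normalized is None:
        raise QpcrError("panel must be geNORM-normalized before stage statistics")
    stages = stages or panel.stages
    stage_names = [s for s in STAGE_ORDER if s in set(stages.values())]
    if len(stage_names) < 2:
        raise QpcrError("need >= 2 stages")
    expected_direction = expected_direction or {}

    report = {}
    for gene in panel.normalized.index:
        row = panel.normalized.loc[gene]
        groups = {}
        detected = {}
        n_per = {}
        for st in stage_names:
            samples = [s for s, lab in stages.items() if lab == st and s in row.index]
            vals = row[samples].dropna().to_numpy(dtype=float)
            n_per[st] = len(samples)
            detected[st] = len(vals)
            groups[st] = vals

        usable = {st: v for st, v in groups.items() if len(v) >= min_detected}
        if len(usable) < 2:
            report[gene] = GeneStats(
                gene=gene, n_per_stage=n_per, detected_per_stage=detected,
                bartlett_p=None, bartlett_p_after=None, transform_applied=False,
                t_one_tailed={}, anova_p=None, letters={}, trend_p=None,
                testable=False, note="insufficient detected values",
            )
            continue
        if all(np.ptp(v) == 0 for v in usable.values()):
            report[gene] = GeneStats(
                gene=gene, n_per_stage=n_per, detected_per_stage=detected,
                bartlett_p=None, bartlett_p_after=None, transform_applied=False,
                t_one_tailed={}, anova_p=None, letters={}, trend_p=None,
                testable=False, note="zero variance in every stage",
            )
            continue

        b_p = float(stats.bartlett(*usable.values()).pvalue)
        transform = b_p < alpha_bartlett
        b_after = None
        if transform:
            usable = {st: log_transform(v) for st, v in usable.items()}
            b_after = float(stats.bartlett(*usable.values()).pvalue)

        t_res = {}
        dir_for = expected_direction.get(gene, {})
        for a, b in CONTRASTS:
            if a not in usable or b not in usable:
                continue
            direction = dir_for.get(f"{a[0].upper()}_vs_{b[0].upper()}", 0)
            if direction > 0:
                alt = "less"  # expect higher in the second stage
            elif direction < 0:
                alt = "greater"
            else:
                # no prior direction: one-tailed in the observed direction
                alt = "less" if usable[b].mean() >= usable[a].mean() else "greater"
            p = float(stats.ttest_ind(usable[a], usable[b], alternative=alt).pvalue)
            t_res[(a, b)] = p

        anova_p = None
        letters = {}
        trend_p = None
        if len(usable) >= 2:
            anova_p = float(stats.f_oneway(*usable.values()).pvalue)
            _, letters = newman_keuls(usable, alpha=alpha)
        if len(usable) >= 3:
            _, trend_p = linear_trend_test([usable[st] for st in stage_names if st in usable])

        report[gene] = GeneStats(
            gene=gene,
            n_per_stage=n_per,
            detected_per_stage=detected,
            bartlett_p=b_p,
            bartlett_p_after=b_after,
            transform_applied=transform,
            t_one_tailed=t_res,
            anova_p=anova_p,
            letters=letters,
            trend_p=trend_p,
            testable=True,
        )
    return StatsReport(genes=report)
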