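"""Two-color loop-design differential expression.

The three follicle stages are compared around a loop (G-P, P-A, G-A) on
two-color arrays, each biological replicate pair hybridized twice with
dyes exchanged. Processing follows the standard two-color chain:

* background subtraction with a small positive floor;
* within-array loess of M = log2(R/G) on A = mean log2 intensity;
* between-array quantile normalization of the single-channel log2
  intensities;
* a per-probe least-squares model with stage coefficients and a dye
  coefficient, with residual variances shrunk toward a common prior by
  empirical-Bayes moment matching, yielding moderated t statistics;
* DEG selection at raw fold change > 1.5, p < 0.05, mean intensity >= 7,
  and a cross-contrast partition of the selected genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

CONTRASTS = ("G_vs_P", "P_vs_A", "G_vs_A")
CONTRAST_STAGES = {
    "G_vs_P": ("growing", "plateau"),
    "P_vs_A": ("plateau", "atretic"),
    "G_vs_A": ("growing", "atretic"),
}
LONG_COLUMNS = ("array_id", "contrast", "dye", "sample_id", "probe_id", "fg", "bg")


class DesignError(ValueError):
    """Raised when the array design is incomplete or inconsistent."""


@dataclass
class TwoColorArraySet:
    """A loop-design collection of two-color arrays in long format.

    ``data`` has one row per (array, channel, probe) with foreground and
    background intensities. Arrays come in dye-swap pairs: the swap mate
    carries the same biological samples with channels exchanged.
    ``truth`` (generator only) holds true per-probe log2 effects per
    contrast.
    """

    data: pd.DataFrame
    truth: pd.DataFrame | None = None

    @classmethod
    def from_long(cls, data: pd.DataFrame, truth: pd.DataFrame | None = None) -> "TwoColorArraySet":
        missing = [c for c in LONG_COLUMNS if c not in data.columns]
        if missing:
            raise DesignError(f"long-format array table is missing columns: {missing}")
        return cls(data=data.copy(), truth=truth)

    @property
    def array_ids(self) -> list:
        return sorted(self.data["array_id"].unique())

    @property
    def probes(self) -> np.ndarray:
        return np.sort(self.data["probe_id"].unique())

    def channels(self) -> pd.DataFrame:
        """One row per (array, dye) with the sample it carries."""
        return (
            self.data[["array_id", "contrast", "dye", "sample_id"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def swap_pairs(self) -> list:
        """Dye-swap mate pairs: arrays carrying the same sample set with
        dye assignments exchanged."""
        ch = self.channels()
        key = {}
        for aid, grp in ch.groupby("array_id"):
            assign = {r.dye: r.sample_id for r in grp.itertuples()}
            key[aid] = (assign.get("green"), assign.get("red"))
        pairs, used = [], set()
        for aid, (g, r) in key.items():
            if aid in used:
                continue
            for bid, (g2, r2) in key.items():
                if bid != aid and bid not in used and (g2, r2) == (r, g):
                    pairs.append((aid, bid))
                    used.update((aid, bid))
                    break
        return pairs

    def swapped(self) -> "TwoColorArraySet":
        """Return a copy with every array's channels exchanged."""
        data = self.data.copy()
        data["dye"] = data["dye"].map({"green": "red", "red": "green"})
        return TwoColorArraySet(data=data, truth=self.truth)


def background_correct(arrays: TwoColorArraySet, floor: float = 0.5) -> TwoColorArraySet:
    """Subtract background from foreground, flooring at ``floor``.

    The floor keeps subsequent log-intensities finite on probes whose
    background exceeds the foreground. Negative raw intensities are
    rejected as a schema violation.
    """
    data = arrays.data.copy()
    if (data["fg"] < 0).any() or (data["bg"] < 0).any():
        raise ValueError("negative raw intensities: foreground/background must be >= 0")
    data["signal"] = np.maximum(data["fg"] - data["bg"], floor)
    return TwoColorArraySet(data=data, truth=arrays.truth)


def _channel_matrix(arrays: TwoColorArraySet, column: str = "signal") -> pd.DataFrame:
    """Pivot to a probes x (array_id, dye) matrix of the given column."""
    if column not in arrays.data.columns:
        raise ValueError(f"column {column!r} not present; run background_correct first")
    mat = arrays.data.pivot_table(index="probe_id", columns=["array_id", "dye"], values=column)
    if mat.isna().any().any():
        raise DesignError("mismatched probe sets across arrays")
    return mat


def normalize_within_loess(
    log2_red: np.ndarray, log2_green: np.ndarray, span: float = 0.3
) -> tuple:
    """Within-array loess normalization of one array's M on A.

    Returns ``(M_normalized, A)``. M is replaced by its residual from a
    loess fit of M ~ A, removing intensity-dependent dye bias (constant
    dye offsets are absorbed as well).
    """
    log2_red = np.asarray(log2_red, dtype=float)
    log2_green = np.asarray(log2_green, dtype=float)
    if len(log2_red) < 50:
        raise ValueError(f"loess normalization needs >= 50 probes, got {len(log2_red)}")
    m = log2_red - log2_green
    a = 0.5 * (log2_red + log2_green)
    fitted = lowess(m, a, frac=span, return_sorted=False)
    return m - fitted, a


def normalize_between_quantile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across columns (ties averaged).

    After normalization every column has the identical sorted vector: the
    mean of the per-rank values across columns. Within-column ranks are
    preserved; tied entries receive the average of their rank span.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 arrays")
    vals = matrix.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_arrays(arrays: TwoColorArraySet, span: float = 0.3, floor: float = 0.5):
    """Full normalization chain: background, within-array loess, quantile.

    Returns ``(M, A, channel_log2)``: per-array normalized M and A
    matrices (probes x arrays) and the quantile-normalized single-channel
    log2 intensity matrix (probes x (array, dye)).
    """
    corrected = background_correct(arrays, floor=floor)
    chan = np.log2(_channel_matrix(corrected))

    array_ids = chan.columns.get_level_values(0).unique()
    m_cols, a_cols = {}, {}
    adjusted = chan.copy()
    for aid in array_ids:
        r = chan[(aid, "red")].to_numpy()
        g = chan[(aid, "green")].to_numpy()
        m_norm, a = normalize_within_loess(r, g, span=span)
        # push the loess correction back into the channels symmetrically
        adjusted[(aid, "red")] = a + m_norm / 2.0
        adjusted[(aid, "green")] = a - m_norm / 2.0

    quant = normalize_between_quantile(adjusted)
    for aid in array_ids:
        r = quant[(aid, "red")]
        g = quant[(aid, "green")]
        m_cols[aid] = r - g
        a_cols[aid] = 0.5 * (r + g)
    M = pd.DataFrame(m_cols)
    A = pd.DataFrame(a_cols)
    return M, A, quant


# ---------------------------------------------------------------------------
# linear model + empirical Bayes
# ---------------------------------------------------------------------------


@dataclass
class ContrastResult:
    """Per-probe statistics for one stage contrast.

    ``log2fc`` follows the loop convention: positive means up-regulated in
    the second item of the contrast name. ``d0``/``s0_sq`` are the prior
    degrees of freedom and prior variance of the moderated model.
    """

    contrast: str
    table: pd.DataFrame  # columns: probe_id, log2fc, A, t, p_value, fdr
    d0: float
    s0_sq: float

    def __post_init__(self):
        p = self.table["p_value"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")


def channel_stage_table(arrays: TwoColorArraySet, stage_of: dict) -> pd.DataFrame:
    """Map each (array, dye) channel to the stage it carries.

    ``stage_of`` maps sample id to stage name. Produces the
    ``channel_stages`` table :func:`fit_loop_model` consumes.
    """
    ch = arrays.channels()
    unknown = sorted(set(ch["sample_id"]) - set(stage_of))
    if unknown:
        raise DesignError(f"no stage assignment for samples: {unknown[:5]}")
    ch = ch.copy()
    ch["stage"] = ch["sample_id"].map(stage_of)
    return ch[["array_id", "dye", "stage"]]


def fit_loop_model(
    M: pd.DataFrame,
    A: pd.DataFrame,
    channel_stages: pd.DataFrame,
) -> dict:
    """Fit the loop linear model and extract the three stage contrasts.

    ``channel_stages`` has one row per (array_id, dye) with a ``stage``
    column naming the stage hybridized in that channel. Per probe the
    model is ``M_a = mu(stage_red) - mu(stage_green) + dye + eps`` with
    the growing stage pinned at zero, fit by least squares across arrays;
    the dye coefficient absorbs gene-independent dye bias that survives
    normalization. Residual variances are shrunk toward a prior (moment
    matching on log variances) and moderated t / two-sided p values are
    reported per contrast. Returns ``{contrast: ContrastResult}``.
    """
    arrays = list(M.columns)
    stage_map = {}
    for r in channel_stages.itertuples():
        stage_map.setdefault(r.array_id, {})[r.dye] = r.stage
    rows = []
    for aid in arrays:
        ch = stage_map.get(aid, {})
        if "red" not in ch or "green" not in ch:
            raise DesignError(f"array {aid} lacks a red/green stage assignment")
        coef = {"plateau": 0.0, "atretic": 0.0}
        for st, sign in ((ch["red"], +1.0), (ch["green"], -1.0)):
            if st not in ("growing", "plateau", "atretic"):
                raise DesignError(f"unknown stage {st!r} on array {aid}")
            if st != "growing":
                coef[st] += sign
        rows.append([coef["plateau"], coef["atretic"], 1.0])
    X = np.asarray(rows)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        seen = {stage_map[a][d] for a in stage_map for d in stage_map[a]}
        missing = {"growing", "plateau", "atretic"} - seen
        raise DesignError(
            f"rank-deficient loop design; missing stage cells: {sorted(missing) if missing else 'dye confounded with stage'}"
        )

    Y = M.to_numpy(dtype=float).T  # arrays x probes
    n, p_params = X.shape
    df_resid = n - p_params
    if df_resid < 1:
        raise DesignError("not enough arrays for residual degrees of freedom")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # params x probes
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / df_resid

    d0, s0_sq = _estimate_prior(s2, df_resid)
    s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid) if np.isfinite(d0) else np.full_like(s2, s0_sq)
    df_total = d0 + df_resid if np.isfinite(d0) else np.inf

    # contrast vectors in (plateau, atretic, dye) coordinates; positive =
    # up in the second item of the contrast name
    cvecs = {
        "G_vs_P": np.array([1.0, 0.0, 0.0]),
        "P_vs_A": np.array([-1.0, 1.0, 0.0]),
        "G_vs_A": np.array([0.0, 1.0, 0.0]),
    }
    a_mean = A.to_numpy(dtype=float).mean(axis=1)
    results = {}
    for name, c in cvecs.items():
        est = c @ beta
        var_scale = float(c @ XtX_inv @ c)
        se = np.sqrt(s2_post * var_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        if np.isfinite(df_total):
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
        fdr = _bh_fdr(p)
        results[name] = ContrastResult(
            contrast=name,
            table=pd.DataFrame(
                {
                    "probe_id": M.index,
                    "log2fc": est,
                    "A": a_mean,
                    "t": t,
                    "p_value": p,
                    "fdr": fdr,
                }
            ).reset_index(drop=True),
            d0=float(d0),
            s0_sq=float(s0_sq),
        )
    results["dye_coefficient"] = float(np.median(beta[2]))
    return results


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (informational column only)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, df: int) -> tuple:
    """Moment-match a scaled inverse chi-square prior to log variances.

    Fits the marginal distribution of log(s^2): its excess variance over
    trigamma(df/2) identifies the prior degrees of freedom d0, and its
    mean identifies the prior variance s0^2. With no excess variance the
    prior is infinite (full shrinkage to the common value).
    """
    s2 = np.clip(np.asarray(s2, dtype=float), 1e-12, None)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    e_var = float(e.var(ddof=1)) * (n - 1) / n - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_t(
    effects: np.ndarray, s2: np.ndarray, var_scale: float, df: int, d0: float, s0_sq: float
):
    """Moderated t statistics for given effects and residual variances.

    Exposed separately so the limiting behaviour (ordinary t as d0 -> 0,
    z-like as d0 -> inf) can be examined directly.
    """
    if np.isinf(d0):
        s2_post = np.full_like(np.asarray(s2, dtype=float), s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)
        df_total = d0 + df
    t = np.asarray(effects) / np.sqrt(s2_post * var_scale)
    return t, df_total


# ---------------------------------------------------------------------------
# DEG selection and partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DEGCriteria:
    """Selection cut-offs: raw symmetric fold change (strict), raw p
    (strict), minimum average log2 intensity (inclusive)."""

    fc_min: float = 1.5
    p_max: float = 0.05
    a_min: float = 7.0

    def __post_init__(self):
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")


def select_degs(result: ContrastResult, crit: DEGCriteria | None = None) -> pd.DataFrame:
    """Select differentially expressed probes for one contrast.

    Keeps probes with raw fold change strictly above ``fc_min`` in either
    direction (|log2FC| > log2 fc_min), p strictly below ``p_max`` and
    average intensity at least ``a_min``; adds a ``direction`` column
    (up = higher in the second item of the contrast).
    """
    crit = crit or DEGCriteria()
    t = result.table
    keep = (
        (np.abs(t["log2fc"]) > math.log2(crit.fc_min))
        & (t["p_value"] < crit.p_max)
        & (t["A"] >= crit.a_min)
    )
    out = t.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


@dataclass
class DEGPartition:
    """Cross-contrast classification of selected genes.

    Genes selected in both transition contrasts (G-P and P-A) are split
    into continuous (same direction across both transitions) and reversal
    (direction flips); the rest are specific to a single transition.
    ``pairwise_shared`` reports intersection sizes for all contrast pairs.
    """

    continuous: set
    reversal: set
    specific_g_vs_p: set
    specific_p_vs_a: set
    totals: dict
    pairwise_shared: dict

    @property
    def shared(self) -> set:
        return self.continuous | self.reversal

    def summary(self) -> dict:
        return {
            "total_G_vs_P": self.totals["G_vs_P"],
            "total_P_vs_A": self.totals["P_vs_A"],
            "specific_G_vs_P": len(self.specific_g_vs_p),
            "specific_P_vs_A": len(self.specific_p_vs_a),
            "shared": len(self.shared),
            "continuous": len(self.continuous),
            "reversal": len(self.reversal),
            "pairwise_shared": dict(self.pairwise_shared),
        }


def partition_contrasts(
    deg_g_vs_p: pd.DataFrame,
    deg_p_vs_a: pd.DataFrame,
    deg_g_vs_a: pd.DataFrame | None = None,
    gene_col: str = "probe_id",
) -> DEGPartition:
    """Classify DEGs across the two transition contrasts.

    A gene selected in both G-P and P-A is continuous when its direction
    agrees (steadily rising or falling across the three stages) and a
    reversal otherwise; genes selected in only one transition are specific
    to it. The identity specific + shared = total holds per contrast.
    """
    dir_gp = _direction_map(deg_g_vs_p, gene_col)
    dir_pa = _direction_map(deg_p_vs_a, gene_col)
    shared = set(dir_gp) & set(dir_pa)
    continuous = {g for g in shared if dir_gp[g] == dir_pa[g]}
    reversal = shared - continuous
    totals = {"G_vs_P": len(dir_gp), "P_vs_A": len(dir_pa)}
    pairwise = {"G_vs_P&P_vs_A": len(shared)}
    if deg_g_vs_a is not None:
        dir_ga = _direction_map(deg_g_vs_a, gene_col)
        totals["G_vs_A"] = len(dir_ga)
        pairwise["G_vs_P&G_vs_A"] = len(set(dir_gp) & set(dir_ga))
        pairwise["P_vs_A&G_vs_A"] = len(set(dir_pa) & set(dir_ga))
    return DEGPartition(
        continuous=continuous,
        reversal=reversal,
        specific_g_vs_p=set(dir_gp) - shared,
        specific_p_vs_a=set(dir_pa) - shared,
        totals=totals,
        pairwise_shared=pairwise,
    )


def _direction_map(deg: pd.DataFrame, gene_col: str) -> dict:
    if deg[gene_col].duplicated().any():
        dups = deg.loc[deg[gene_col].duplicated(), gene_col].tolist()
        raise ValueError(f"duplicate gene ids within a DEG table: {dups[:5]}")
    if "direction" in deg.columns:
        return dict(zip(deg[gene_col], deg["direction"]))
    return dict(zip(deg[gene_col], np.where(deg["log2fc"] > 0, "up", "down")))


# ---------------------------------------------------------------------------
# BGA input extraction
# ---------------------------------------------------------------------------


def bga_input_from_arrays(arrays: TwoColorArraySet, stage_of: dict, span: float = 0.3):
    """Build the ordination input from green-channel data.

    ``stage_of`` maps sample id to stage. The green channel of every
    slide is extracted after full normalization; within a dye-swap pair
    the two green channels carry the pair's two stages once each, so a
    full loop with four replicate pairs per contrast yields exactly eight
    data sets per stage. Returns ``(matrix probes x data sets, stage
    labels aligned with the columns)``.
    """
    _, _, quant = normalize_arrays(arrays, span=span)
    ch = arrays.channels()
    chan_samples = {(r.array_id, r.dye): r.sample_id for r in ch.itertuples()}

    cols, labels, names = [], [], []
    for aid in arrays.array_ids:
        sample = chan_samples[(aid, "green")]
        if sample not in stage_of:
            raise DesignError(f"no stage assignment for sample {sample!r}")
        cols.append(quant[(aid, "green")])
        labels.append(stage_of[sample])
        names.append(f"{aid}_green")
    mat = pd.concat(cols, axis=1)
    mat.columns = names
    return mat, labels
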