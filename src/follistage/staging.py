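"""Follicle staging from normalized DNA-content phase proportions.

Follicles are ranked by the score ``x = G2 + S + G1 - subG1`` computed on
normalized proportions (where it reduces to ``100 - 2 * subG1``, i.e. the
ranking is equivalent to ranking by apoptotic fraction). After RIN-based
QC exclusion, the top ``k`` ranks are called growing, the bottom ``k``
atretic, and ``k`` ranks centered in the remainder plateau; the leftover
boundary samples are excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from follistage.cytometry import PhaseProfile

STAGE_LABELS = ("growing", "plateau", "atretic")
EXCLUDED_QC = "excluded_qc"
EXCLUDED_BOUNDARY = "excluded_boundary"
UNASSIGNED = "unassigned"


class StagingError(ValueError):
    """Raised when staging preconditions are violated."""


@dataclass(frozen=True)
class FollicleSample:
    """One follicle with its phase profile and (eventual) stage call."""

    sample_id: str
    diameter_mm: float
    rin: float
    profile: PhaseProfile
    x_score: float | None = None
    stage: str = UNASSIGNED

    def __post_init__(self):
        if self.stage not in (*STAGE_LABELS, EXCLUDED_QC, EXCLUDED_BOUNDARY, UNASSIGNED):
            raise StagingError(f"unknown stage label {self.stage!r}")


@dataclass(frozen=True)
class StagingConfig:
    group_size: int = 7
    rin_min: float = 7.0
    require_normalized: bool = True

    def __post_init__(self):
        if self.group_size < 1:
            raise StagingError("group_size must be >= 1")


@dataclass(frozen=True)
class StagedCohort:
    """Outcome of stage assignment over a cohort."""

    samples: list
    config: StagingConfig

    def by_stage(self, stage: str) -> list:
        return [s for s in self.samples if s.stage == stage]

    @property
    def counts(self) -> dict:
        out: dict = {}
        for s in self.samples:
            out[s.stage] = out.get(s.stage, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "diameter_mm": [s.diameter_mm for s in self.samples],
                "rin": [s.rin for s in self.samples],
                "p_subG1": [s.profile.p_subG1 for s in self.samples],
                "p_G1": [s.profile.p_G1 for s in self.samples],
                "p_S": [s.profile.p_S for s in self.samples],
                "p_G2": [s.profile.p_G2 for s in self.samples],
                "x_score": [s.x_score for s in self.samples],
                "stage": [s.stage for s in self.samples],
            }
        )


def compute_x(profile: PhaseProfile, allow_raw: bool = False) -> float:
    """Score a profile: ``x = p_G2 + p_S + p_G1 - p_subG1``.

    On normalized input this equals ``100 - 2 * p_subG1``: healthy
    follicles (no apoptosis) score 100 and the score falls by two points
    per percent of sub-G1 events. Raises on un-normalized profiles unless
    ``allow_raw`` (sensitivity-analysis mode), to avoid silently mixing
    scales across samples.
    """
    if not profile.normalized and not allow_raw:
        raise StagingError("x score requires a normalized profile (or allow_raw=True)")
    return profile.p_G2 + profile.p_S + profile.p_G1 - profile.p_subG1


def assign_stages(samples: list, cfg: StagingConfig | None = None) -> StagedCohort:
    """Partition a cohort into growing / plateau / atretic groups of size k.

    Samples with ``rin < rin_min`` are excluded first (QC). Remaining
    samples are ranked by x descending, ties broken by sample_id
    ascending. The top k are growing, the bottom k atretic, and the k
    ranks centered on the median of the remainder plateau (when the
    excess is odd the extra exclusion falls on the growing side).
    Everything else is marked as a boundary exclusion.
    """
    cfg = cfg or StagingConfig()
    k = cfg.group_size

    scored = []
    for s in samples:
        x = s.x_score if s.x_score is not None else compute_x(s.profile, allow_raw=not cfg.require_normalized)
        scored.append(replace(s, x_score=x))

    qc_fail = [replace(s, stage=EXCLUDED_QC) for s in scored if s.rin < cfg.rin_min]
    eligible = [s for s in scored if s.rin >= cfg.rin_min]
    if len(eligible) < 3 * k:
        raise StagingError(
            f"need at least {3 * k} QC-passing samples for k={k}, have {len(eligible)} "
            f"(deficit {3 * k - len(eligible)})"
        )

    ranked = sorted(eligible, key=lambda s: (-s.x_score, s.sample_id))
    growing = ranked[:k]
    atretic = ranked[-k:]
    middle = ranked[k:-k]  # length m = n - 2k >= k
    m = len(middle)
    # center the plateau window on the median rank of the remainder;
    # odd excess drops the extra sample on the growing (top) side
    start = (m - k + 1) // 2
    plateau = middle[start : start + k]
    boundary = middle[:start] + middle[start + k :]

    out = (
        [replace(s, stage="growing") for s in growing]
        + [replace(s, stage="plateau") for s in plateau]
        + [replace(s, stage="atretic") for s in atretic]
        + [replace(s, stage=EXCLUDED_BOUNDARY) for s in boundary]
        + qc_fail
    )
    order = {s.sample_id: i for i, s in enumerate(samples)}
    out.sort(key=lambda s: order[s.sample_id])
    return StagedCohort(samples=out, config=cfg)
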