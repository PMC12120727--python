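"""Depth normalization, cross-round enrichment, and candidate selection.

A sequence is a candidate if it sits in the top-k of an arm's final pool
and its reads-per-million abundance increased (strictly) between the
early and final rounds of that arm.  Sequences passing in several arms
(injury models) are prioritized over single-arm hits, mirroring a
selection that looks for binders common to multiple injury states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .library import PoolTable

__all__ = [
    "SelectionCriteria",
    "EnrichmentRecord",
    "Candidate",
    "CandidateSet",
    "normalize_rpm",
    "compute_enrichment",
    "select_candidates",
    "write_candidate_report",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Tunable candidate-selection thresholds.

    top_k: how many of the final pool's most abundant sequences to score.
    min_fold: an "increase in abundance" means fold_change strictly > this.
    min_arms: minimum number of arms for the priority (multi-arm) tier.
    pseudocount_rpm: RPM floor for sequences absent from the early pool
        (about half of one read at 2M depth), keeping fold changes finite.
    """

    top_k: int = 100
    min_fold: float = 1.0
    min_arms: int = 2
    pseudocount_rpm: float = 0.5

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_arms < 1:
            raise ValueError("min_arms must be >= 1")
        if self.pseudocount_rpm <= 0:
            raise ValueError("pseudocount_rpm must be > 0")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Early-vs-final abundance comparison for one sequence in one arm."""

    sequence: str
    arm: str
    rank_final: int
    rpm_early: float
    rpm_final: float
    fold_change: float


@dataclass(frozen=True)
class Candidate:
    name: str
    sequence: str
    arms_present: frozenset[str]
    fold_changes: dict[str, float] = field(hash=False, default_factory=dict)
    best_arm: str = ""
    best_rank: int = 0


@dataclass
class CandidateSet:
    """Ordered candidates (multi-arm tier first) plus the criteria used."""

    candidates: list[Candidate]
    criteria: SelectionCriteria

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.candidates]

    @property
    def sequences(self) -> list[str]:
        return [c.sequence for c in self.candidates]


def normalize_rpm(table: PoolTable) -> PoolTable:
    """Attach reads-per-million to a count table.

    rpm(s) = count(s) / total_reads * 1e6, so the rpm column sums to 1e6.
    """
    if table.total_reads == 0:
        raise ValueError("empty pool: cannot normalize zero total reads")
    scale = 1e6 / table.total_reads
    rpm = {seq: count * scale for seq, count in table.counts.items()}
    return replace(table, rpm=rpm)


def _require_rpm(table: PoolTable, which: str) -> dict[str, float]:
    if table.rpm is None:
        raise ValueError(f"{which} pool is not normalized; call normalize_rpm first")
    return table.rpm


def compute_enrichment(
    early: PoolTable, final: PoolTable, criteria: SelectionCriteria, arm: str = ""
) -> list[EnrichmentRecord]:
    """Score the final pool's top-k sequences against the early pool.

    fold_change = rpm_final / max(rpm_early, pseudocount_rpm).  Ordering
    is deterministic: descending rpm_final, ties broken lexicographically
    by sequence.
    """
    early_rpm = _require_rpm(early, "early")
    final_rpm = _require_rpm(final, "final")
    arm = arm or final.pool_id[1]
    ranked = sorted(final_rpm.items(), key=lambda kv: (-kv[1], kv[0]))
    records = []
    for rank, (seq, rpm_final) in enumerate(ranked[: criteria.top_k], start=1):
        rpm_early = early_rpm.get(seq, 0.0)
        denom = max(rpm_early, criteria.pseudocount_rpm)
        records.append(
            EnrichmentRecord(
                sequence=seq,
                arm=arm,
                rank_final=rank,
                rpm_early=rpm_early,
                rpm_final=rpm_final,
                fold_change=rpm_final / denom,
            )
        )
    return records


def select_candidates(
    records_by_arm: dict[str, list[EnrichmentRecord]],
    criteria: SelectionCriteria,
    arm_prefixes: dict[str, str] | None = None,
    multi_arm_prefix: str = "S",
) -> CandidateSet:
    """Apply the enrichment filter per arm, then prioritize multi-arm hits.

    A sequence passes in an arm when its fold_change there is strictly
    above ``criteria.min_fold``.  Sequences passing in at least
    ``min_arms`` arms form the priority tier, ordered by their best
    (highest) final RPM across arms; the single-arm tier follows, ordered
    the same way.  Ties break lexicographically by sequence.

    Names follow the rank-in-arm convention: multi-arm candidates get
    ``multi_arm_prefix`` + consecutive number; single-arm candidates get
    their arm's prefix + their abundance rank in that arm.
    """
    if not records_by_arm:
        raise ValueError("at least one arm is required")
    arm_prefixes = arm_prefixes or {
        arm: arm[:1].upper() or "X" for arm in records_by_arm
    }

    passed: dict[str, dict[str, EnrichmentRecord]] = {}
    for arm, records in records_by_arm.items():
        for rec in records:
            if rec.fold_change > criteria.min_fold:
                passed.setdefault(rec.sequence, {})[arm] = rec

    def sort_key(seq: str):
        best = max(r.rpm_final for r in passed[seq].values())
        return (-best, seq)

    multi = sorted(
        (s for s, arms in passed.items() if len(arms) >= criteria.min_arms),
        key=sort_key,
    )
    single = sorted(
        (s for s, arms in passed.items() if len(arms) < criteria.min_arms),
        key=sort_key,
    )

    candidates: list[Candidate] = []
    for i, seq in enumerate(multi, start=1):
        arms = passed[seq]
        best_arm = max(arms, key=lambda a: (arms[a].rpm_final, a))
        candidates.append(
            Candidate(
                name=f"{multi_arm_prefix}{i}",
                sequence=seq,
                arms_present=frozenset(arms),
                fold_changes={a: r.fold_change for a, r in arms.items()},
                best_arm=best_arm,
                best_rank=arms[best_arm].rank_final,
            )
        )
    for seq in single:
        (arm, rec), = passed[seq].items()
        candidates.append(
            Candidate(
                name=f"{arm_prefixes[arm]}{rec.rank_final}",
                sequence=seq,
                arms_present=frozenset({arm}),
                fold_changes={arm: rec.fold_change},
                best_arm=arm,
                best_rank=rec.rank_final,
            )
        )
    names = [c.name for c in candidates]
    if len(names) != len(set(names)):  # two single-arm tiers cannot collide per arm
        seen: dict[str, int] = {}
        unique = []
        for c in candidates:
            n = seen.get(c.name, 0)
            seen[c.name] = n + 1
            unique.append(replace(c, name=c.name if n == 0 else f"{c.name}.{n}"))
        candidates = unique
    return CandidateSet(candidates=candidates, criteria=criteria)


def write_candidate_report(cset: CandidateSet, path) -> None:
    """TSV report: name, sequence, arms, per-arm fold changes, best rank."""
    rows = [
        {
            "name": c.name,
            "sequence": c.sequence,
            "n_arms": len(c.arms_present),
            "arms_present": ",".join(sorted(c.arms_present)),
            "best_arm": c.best_arm,
            "best_rank": c.best_rank,
            "fold_changes": ";".join(
                f"{a}={c.fold_changes[a]:.4g}" for a in sorted(c.fold_changes)
            ),
        }
        for c in cset
    ]
    pd.DataFrame(
        rows,
        columns=[
            "name", "sequence", "n_arms", "arms_present",
            "best_arm", "best_rank", "fold_changes",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
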