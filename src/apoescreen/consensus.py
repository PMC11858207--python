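"""Ensemble-docking consensus ranking and screening diagnostics.

The central statistic is the consensus score of a ligand screened against an
ensemble of receptor conformations that respond *oppositely* to binders:

    consensus_score = mean(rank over holo-ApoE4 structures)
                      / mean(rank over free-ApoE4 structures)

Docking ranks on ligand-bound (holo) ApoE4 structures correlate positively
with true affinity, while ranks on free ApoE4 structures — whose Trp34
sidechain closes the pocket — correlate negatively.  Taking the ratio
rewards ligands that dock well where binders should and poorly where they
should not; lower is better.  The module also provides rank/Kd correlation
diagnostics, top-fraction enrichment, shape-query combination, hitlist
intersection and censoring-aware Kd triage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Censor, KdRecord

__all__ = [
    "CATEGORIES",
    "ScoreMatrix",
    "ConsensusEntry",
    "DiagnosticsResult",
    "EnrichmentResult",
    "HitList",
    "rank_scores",
    "consensus_score",
    "build_consensus_table",
    "consensus_frame",
    "correlation_diagnostics",
    "enrichment",
    "combine_shape_queries",
    "intersect_hitlists",
    "kd_triage",
]

CATEGORIES = ("apoE3", "free-apoE4", "holo-apoE4")


@dataclass
class ScoreMatrix:
    """Ligand × structure matrix of docking scores or ranks.

    ``values`` is a DataFrame indexed by ligand id with one column per
    structure id; ``categories`` maps every column to its ensemble category.
    ``value_kind`` is ``"score"`` (kcal/mol, lower better) or ``"rank"``
    (1 = best).
    """

    values: pd.DataFrame
    categories: Mapping[str, str]
    value_kind: str = "score"

    def __post_init__(self) -> None:
        if self.value_kind not in {"score", "rank"}:
            raise ValueError(f"value_kind must be 'score' or 'rank', got {self.value_kind!r}")
        missing = [c for c in self.values.columns if c not in self.categories]
        if missing:
            raise ValueError(f"structure columns without a category: {missing}")
        bad = {c: k for c, k in self.categories.items() if k not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories {bad}; expected one of {CATEGORIES}")
        if self.value_kind == "rank":
            for col in self.values.columns:
                v = self.values[col].dropna()
                if (v <= 0).any():
                    raise ValueError(f"column {col}: ranks must be positive")

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.values.index)

    def columns_of(self, category: str) -> list[str]:
        return [c for c in self.values.columns if self.categories[c] == category]

    def to_ranks(self) -> "ScoreMatrix":
        """Per-column ranking (rank 1 = best docking score, average ties)."""
        if self.value_kind == "rank":
            return self
        ranked = self.values.apply(
            lambda col: rank_scores(col.to_numpy(), "lower_better"), axis=0
        )
        ranked = pd.DataFrame(ranked, index=self.values.index, columns=self.values.columns)
        return ScoreMatrix(values=ranked, categories=dict(self.categories), value_kind="rank")


def rank_scores(values, direction: str = "lower_better") -> np.ndarray:
    """Rank values with average ties; rank 1 = best under ``direction``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty array")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values cannot be ranked")
    if direction == "lower_better":
        return stats.rankdata(v, method="average")
    if direction == "higher_better":
        return stats.rankdata(-v, method="average")
    raise ValueError(f"direction must be 'lower_better' or 'higher_better', got {direction!r}")


def consensus_score(holo_ranks: Sequence[float], free_ranks: Sequence[float]) -> float:
    """Ratio of average holo rank to average free rank (lower = better)."""
    holo = np.asarray(holo_ranks, dtype=float)
    free = np.asarray(free_ranks, dtype=float)
    if holo.size == 0 or free.size == 0:
        raise ValueError("both holo and free ranks are required")
    if np.any(holo <= 0) or np.any(free <= 0):
        raise ValueError("ranks must be strictly positive")
    return float(holo.mean() / free.mean())


@dataclass(frozen=True)
class ConsensusEntry:
    ligand_id: str
    avg_holo_rank: float
    avg_free_rank: float
    consensus_score: float
    consensus_rank: float


def build_consensus_table(matrix: ScoreMatrix) -> list[ConsensusEntry]:
    """Consensus entry per ligand, library-ranked by ascending consensus score.

    Scores are first converted to per-column ranks if needed. Requires at
    least one holo-apoE4 and one free-apoE4 column.
    """
    ranks = matrix.to_ranks()
    holo_cols = ranks.columns_of("holo-apoE4")
    free_cols = ranks.columns_of("free-apoE4")
    for name, cols in (("holo-apoE4", holo_cols), ("free-apoE4", free_cols)):
        if not cols:
            raise ValueError(f"score matrix has no {name} column")
    holo_avg = ranks.values[holo_cols].mean(axis=1)
    free_avg = ranks.values[free_cols].mean(axis=1)
    if holo_avg.isna().any() or free_avg.isna().any():
        bad = list(ranks.values.index[holo_avg.isna() | free_avg.isna()])
        raise ValueError(f"missing holo/free ranks for ligands: {bad}")
    score = holo_avg / free_avg
    lib_rank = rank_scores(score.to_numpy(), "lower_better")
    return [
        ConsensusEntry(
            ligand_id=str(lig),
            avg_holo_rank=float(holo_avg.loc[lig]),
            avg_free_rank=float(free_avg.loc[lig]),
            consensus_score=float(score.loc[lig]),
            consensus_rank=float(lib_rank[i]),
        )
        for i, lig in enumerate(ranks.values.index)
    ]


def consensus_frame(entries: Sequence[ConsensusEntry]) -> pd.DataFrame:
    """Consensus table as a DataFrame sorted by library rank."""
    df = pd.DataFrame([e.__dict__ for e in entries])
    return df.sort_values("consensus_rank", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Correlation diagnostics
# ---------------------------------------------------------------------------

_CORR_FUNCS = {
    "pearson": lambda a, b: stats.pearsonr(a, b).statistic,
    "spearman": lambda a, b: stats.spearmanr(a, b).statistic,
    "kendall": lambda a, b: stats.kendalltau(a, b).statistic,
}


@dataclass
class DiagnosticsResult:
    per_structure: dict[str, float]
    consensus: float
    method: str
    kd_policy: str
    n_used: int


def _kd_value(record: KdRecord, policy: str) -> float | None:
    """Numeric Kd under a censoring policy; None means the record is dropped."""
    if record.censor is Censor.NO_BINDING:
        return None
    if record.censor is Censor.NONE:
        return record.kd_um
    if policy == "substitute":
        return record.kd_um
    if policy == "midpoint":
        # bounded entries mapped to a representative interior value
        return record.kd_um / 2 if record.censor is Censor.BELOW else record.kd_um * 2
    if policy == "drop":
        return None
    raise ValueError(f"unknown kd_policy {policy!r}")


def correlation_diagnostics(
    matrix: ScoreMatrix,
    kd_records: Sequence[KdRecord],
    method: str = "spearman",
    kd_policy: str = "substitute",
) -> DiagnosticsResult:
    """Correlate each structure's ranks — and the consensus score — with Kd.

    Positive coefficients mean good docking ranks go with tight binding.
    Censored Kd entries enter according to ``kd_policy`` (``substitute``:
    use the bound value; ``midpoint``: interior representative; ``drop``).
    """
    if method not in _CORR_FUNCS:
        raise ValueError(f"method must be one of {sorted(_CORR_FUNCS)}, got {method!r}")
    kd_map: dict[str, float] = {}
    for r in kd_records:
        v = _kd_value(r, kd_policy)
        if v is not None:
            kd_map[r.ligand_id] = v
    ranks = matrix.to_ranks()
    common = [lig for lig in ranks.values.index if str(lig) in kd_map]
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 ligands with usable Kd under policy {kd_policy!r}, "
            f"got {len(common)}"
        )
    kd = np.array([kd_map[str(lig)] for lig in common])
    corr = _CORR_FUNCS[method]
    per_structure = {
        col: float(corr(ranks.values.loc[common, col].to_numpy(), kd))
        for col in ranks.values.columns
    }
    sub = ScoreMatrix(ranks.values.loc[common], dict(matrix.categories), "rank")
    entries = build_consensus_table(sub)
    cscore = np.array([e.consensus_score for e in entries])
    return DiagnosticsResult(
        per_structure=per_structure,
        consensus=float(corr(cscore, kd)),
        method=method,
        kd_policy=kd_policy,
        n_used=len(common),
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    top_fraction: float
    n_actives_in_top: int
    n_actives: int
    library_size: int
    enrichment_factor: float
    min_fraction_containing_all_actives: float


def enrichment(
    entries: Sequence[ConsensusEntry],
    actives: Iterable[str],
    top_fraction: float,
) -> EnrichmentResult:
    """Early-recognition metrics for a consensus-ranked library."""
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    active_set = {str(a) for a in actives}
    ids = {e.ligand_id for e in entries}
    unknown = active_set - ids
    if unknown:
        raise ValueError(f"actives not present in library: {sorted(unknown)}")
    n = len(entries)
    n_top = max(1, int(math.floor(top_fraction * n + 1e-9)))
    active_ranks = [e.consensus_rank for e in entries if e.ligand_id in active_set]
    if not active_ranks:
        raise ValueError("no actives supplied")
    n_in_top = sum(1 for r in active_ranks if r <= n_top)
    ef = (n_in_top / len(active_ranks)) / top_fraction
    return EnrichmentResult(
        top_fraction=top_fraction,
        n_actives_in_top=n_in_top,
        n_actives=len(active_ranks),
        library_size=n,
        enrichment_factor=ef,
        min_fraction_containing_all_actives=max(active_ranks) / n,
    )


# ---------------------------------------------------------------------------
# Shape-query combination and hitlist intersection
# ---------------------------------------------------------------------------

@dataclass
class HitList:
    """Ligand ids strictly ordered by descending score.

    Ties are broken by mean score across queries, then lexicographic id,
    so the ordering is deterministic.
    """

    entries: list[tuple[str, float]]

    @property
    def ids(self) -> list[str]:
        return [lig for lig, _ in self.entries]

    def top(self, n: int) -> list[str]:
        if n > len(self.entries):
            raise ValueError(f"requested top {n} of a {len(self.entries)}-entry hitlist")
        return self.ids[:n]


def combine_shape_queries(
    tables: Sequence[pd.Series | Mapping[str, float]],
    mode: str = "intersection",
) -> HitList:
    """Combine per-query shape-similarity scores into one hitlist.

    Scores are higher-better similarities (TanimotoCombo-style). The combined
    score is the *maximum* over queries, so one strong overlay suffices.
    ``mode="intersection"`` (default) requires ligands scored by every query;
    ``mode="union"`` keeps all ligands, combining over available queries.
    """
    if not tables:
        raise ValueError("at least one query table is required")
    series = [pd.Series(t, dtype=float) for t in tables]
    for i, s in enumerate(series):
        if s.index.duplicated().any():
            raise ValueError(f"query table {i} has duplicate ligand ids")
    id_sets = [set(map(str, s.index)) for s in series]
    common = set.intersection(*id_sets)
    if mode == "intersection":
        if not common:
            raise ValueError(
                "query tables share no ligands; pass mode='union' to combine anyway"
            )
        ids = common
    elif mode == "union":
        ids = set.union(*id_sets)
    else:
        raise ValueError(f"mode must be 'intersection' or 'union', got {mode!r}")
    wide = pd.concat([s.rename(i) for i, s in enumerate(series)], axis=1)
    wide.index = wide.index.map(str)
    wide = wide.loc[sorted(ids)]
    combined = wide.max(axis=1)
    mean_score = wide.mean(axis=1)
    order = sorted(
        combined.index,
        key=lambda lig: (-combined[lig], -mean_score[lig], lig),
    )
    return HitList(entries=[(lig, float(combined[lig])) for lig in order])


def intersect_hitlists(a: HitList | Sequence[str], b: HitList | Sequence[str],
                       n: int) -> list[str]:
    """Common ligands of two top-``n`` lists, ordered by summed list position."""
    ids_a = a.top(n) if isinstance(a, HitList) else list(a)[:n]
    ids_b = b.top(n) if isinstance(b, HitList) else list(b)[:n]
    if len(ids_a) < n or len(ids_b) < n:
        raise ValueError(f"both lists must have at least {n} entries")
    pos_a = {lig: i for i, lig in enumerate(ids_a)}
    pos_b = {lig: i for i, lig in enumerate(ids_b)}
    common = set(ids_a) & set(ids_b)
    return sorted(common, key=lambda lig: (pos_a[lig] + pos_b[lig], lig))


# ---------------------------------------------------------------------------
# Kd triage
# ---------------------------------------------------------------------------

def kd_triage(
    records: Sequence[KdRecord],
    threshold_um: float,
    proteins: Sequence[str] | None = None,
) -> list[str]:
    """Ligands whose Kd beats ``threshold_um`` against every requested protein.

    A record passes if it is uncensored with Kd < threshold, or censored
    *below* a bound ≤ threshold (the true Kd is then smaller still).
    ``>bound`` entries and "No binding" never pass. ``proteins`` defaults to
    all proteins present in the records.
    """
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    if proteins is None:
        seen = {r.protein for r in records}
        proteins = sorted(p for p in seen if p is not None) or [None]  # type: ignore[list-item]
    by_ligand: dict[str, dict[str | None, bool]] = {}
    order: list[str] = []
    for r in records:
        if r.ligand_id not in by_ligand:
            by_ligand[r.ligand_id] = {}
            order.append(r.ligand_id)
        passes = (
            (r.censor is Censor.NONE and r.kd_um < threshold_um)
            or (r.censor is Censor.BELOW and r.kd_um <= threshold_um)
        )
        prev = by_ligand[r.ligand_id].get(r.protein, False)
        by_ligand[r.ligand_id][r.protein] = prev or passes
    return [
        lig for lig in order
        if all(by_ligand[lig].get(p, False) for p in proteins)
    ]
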