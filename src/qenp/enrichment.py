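"""Over-representation analysis over GMT gene-set collections.

Self-contained ORA: upper-tail hypergeometric p-values (computed via the
survival function in log-stable form), Benjamini-Hochberg step-up
adjustment, and the bridge to the weight engine — each result row carries
the summed target weight of its scored members and a before/after rank
pair once re-ordered.

Default universe is the union of all symbols in the loaded collection;
set-size gates default to [5, 500]; rows with zero overlap are dropped
before ranking.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from scipy.stats import hypergeom

from qenp.errors import FormatError, ValidationError
from qenp.target_sets import TargetSet, make_target_set
from qenp.weight_engine import (
    TargetWeight,
    aggregate_pathway_weight,
    rank_shift_report,
    rerank_by_weight,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 500
DEFAULT_TOP_M = 30


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        members = frozenset(m.strip().upper() for m in self.members if m.strip())
        object.__setattr__(self, "members", members)
        if not members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered gene-set collection with a namespace label (BP/CC/MF/pathway)."""

    sets: tuple[GeneSet, ...]
    namespace: str = "pathway"

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate set_id {dup!r} in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def all_symbols(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested gene set with ORA statistics and weight-ranking fields.

    ``k``: overlap count, ``n``: hit-list size in universe, ``K``: set size
    in universe, ``N``: universe size. ``p_weight`` is the summed target
    weight of the overlapping members; ``rank_before`` is the ascending
    p-value rank and ``rank_after`` the post-re-ranking position.
    """

    set_id: str
    description: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    p_adjusted: float
    p_weight: float = 0.0
    rank_before: int = 0
    rank_after: int | None = None
    members_hit: frozenset[str] = field(default_factory=frozenset)

    @property
    def delta(self) -> int | None:
        if self.rank_after is None:
            return None
        return self.rank_before - self.rank_after


def read_gmt(path: str | Path, namespace: str = "pathway") -> GeneSetCollection:
    """Parse a standard GMT file: ``set_id<TAB>description<TAB>member...``.

    Members are upper-cased and deduplicated; line order is preserved.
    A malformed line (< 3 fields) or an empty file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        sets.append(
            GeneSet(
                set_id=fields[0].strip(),
                description=fields[1].strip(),
                members=frozenset(fields[2:]),
            )
        )
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=tuple(sets), namespace=namespace)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([s.set_id, s.description, *sorted(s.members)])
        for s in collection.sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts marked items among ``n`` draws without replacement from a
    population of ``N`` containing ``K`` marked items. Uses the survival
    function, which scipy evaluates stably in log space for large N.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted(i) = min over j >= i (sorted order) of p(j) * m / j, clipped
    at 1. Raises on p outside (0, 1].
    """
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p} outside (0, 1]")
    m = len(p_values)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p_values[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def run_ora(
    hits: TargetSet,
    collection: GeneSetCollection,
    universe: TargetSet | None = None,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation test per gene set.

    The universe defaults to every symbol in the collection. Hit symbols
    outside the universe are dropped (logged). Sets are tested when their
    in-universe size falls within ``[min_size, max_size]``; rows with zero
    overlap are excluded. ``rank_before`` is the ascending p-value rank
    with ties broken by ``set_id``.
    """
    if universe is None:
        universe = make_target_set("collection", collection.all_symbols())
    if not universe.symbols:
        raise ValidationError("universe is empty")
    in_universe = hits.symbols & universe.symbols
    dropped = len(hits.symbols) - len(in_universe)
    if dropped:
        logger.info("dropped %d hit symbols outside the universe", dropped)
    N = len(universe.symbols)
    n = len(in_universe)

    rows: list[EnrichmentRow] = []
    for gs in collection:
        members_in_universe = gs.members & universe.symbols
        K = len(members_in_universe)
        if not (min_size <= K <= max_size):
            continue
        overlap = members_in_universe & in_universe
        k = len(overlap)
        if k == 0:
            continue
        p = hypergeometric_p(k, n, K, N)
        rows.append(
            EnrichmentRow(
                set_id=gs.set_id,
                description=gs.description,
                k=k, n=n, K=K, N=N,
                p_value=p,
                p_adjusted=p,  # overwritten below
                members_hit=frozenset(overlap),
            )
        )
    if not rows:
        return []
    adjusted = bh_adjust([r.p_value for r in rows])
    rows = [replace(r, p_adjusted=adj) for r, adj in zip(rows, adjusted)]
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    return [replace(r, rank_before=i) for i, r in enumerate(rows, start=1)]


def attach_pathway_weights(
    rows: Sequence[EnrichmentRow],
    target_weights: Sequence[TargetWeight] | Mapping[str, float],
) -> list[EnrichmentRow]:
    """Fill ``p_weight`` per row: summed ti over the row's hit members."""
    return [
        replace(
            r,
            p_weight=aggregate_pathway_weight(
                target_weights, r.members_hit, set_id=r.set_id
            ).p_weight,
        )
        for r in rows
    ]


def enrich_and_rerank(
    hits: TargetSet,
    target_weights: Sequence[TargetWeight] | Mapping[str, float],
    collection: GeneSetCollection,
    universe: TargetSet | None = None,
    top_m: int = DEFAULT_TOP_M,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> list[EnrichmentRow]:
    """ORA, weight attachment, and weight re-ranking in one pass.

    Re-ranking happens over the full result table; the top ``top_m`` rows
    by weight are returned (``top_m=None`` returns everything).
    """
    rows = run_ora(hits, collection, universe, min_size=min_size, max_size=max_size)
    rows = attach_pathway_weights(rows, target_weights)
    rows = rerank_by_weight(rows)
    if top_m is not None:
        rows = rows[:top_m]
    return rows


RESULT_COLUMNS = (
    "set_id", "description", "k", "K", "n", "N",
    "p_value", "p_adjusted", "p_weight", "rank_before", "rank_after", "delta",
)


def write_enrichment_table(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RESULT_COLUMNS)
        for r in rows:
            w.writerow([
                r.set_id, r.description, r.k, r.K, r.n, r.N,
                f"{r.p_value:.6g}", f"{r.p_adjusted:.6g}", f"{r.p_weight:.6g}",
                r.rank_before,
                "" if r.rank_after is None else r.rank_after,
                "" if r.delta is None else r.delta,
            ])


def read_enrichment_table(path: str | Path) -> list[EnrichmentRow]:
    """Read back a results TSV written by :func:`write_enrichment_table`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        names = [n.strip() for n in (reader.fieldnames or [])]
        for col in ("set_id", "p_value", "p_weight", "rank_before"):
            if col not in names:
                raise FormatError(f"{path}: missing required column {col!r}")
        rows = []
        for r in reader:
            rows.append(
                EnrichmentRow(
                    set_id=r["set_id"],
                    description=r.get("description", ""),
                    k=int(r.get("k", 0) or 0),
                    n=int(r.get("n", 0) or 0),
                    K=int(r.get("K", 0) or 0),
                    N=int(r.get("N", 0) or 0),
                    p_value=float(r["p_value"]),
                    p_adjusted=float(r.get("p_adjusted") or r["p_value"]),
                    p_weight=float(r["p_weight"]),
                    rank_before=int(r["rank_before"]),
                    rank_after=int(r["rank_after"]) if r.get("rank_after") else None,
                )
            )
    return rows


__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentRow",
    "read_gmt",
    "write_gmt",
    "hypergeometric_p",
    "bh_adjust",
    "run_ora",
    "attach_pathway_weights",
    "enrich_and_rerank",
    "rerank_by_weight",
    "rank_shift_report",
    "write_enrichment_table",
]
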