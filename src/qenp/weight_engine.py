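"""Quantity-effect weight propagation.

The chain is: per-compound weight ``ci = rel_content_pct * ob`` (relative
content times oral-bioavailability probability, a proxy for the amount of a
component reaching the bloodstream); per-target weight ``ti = sum of ci``
over compounds mapped to the target; per-pathway weight ``p_weight = sum of
ti`` over the pathway's scored member targets. Enrichment rows are then
re-ordered by descending pathway weight.

All downstream uses are rank-based, so ``ci`` is scale-invariant: contents
can be used on the percent scale exactly as printed in a composition table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from qenp.compound_table import Compound
from qenp.errors import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from qenp.enrichment import EnrichmentRow
    from qenp.network_analysis import CompoundTargetMap


@dataclass(frozen=True)
class ObRecord:
    """Oral-bioavailability probability for one compound (fraction in [0,1])."""

    compound_id: str
    ob: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ob <= 1.0):
            raise ValidationError(
                f"OB for {self.compound_id!r} must lie in [0, 1], got {self.ob}"
            )


@dataclass(frozen=True)
class ComponentWeight:
    """Blood-inflow weight of one compound: ci = rel_content_pct * ob."""

    compound_id: str
    ci: float

    def __post_init__(self) -> None:
        if self.ci < 0:
            raise ValidationError(f"ci must be >= 0, got {self.ci}")


@dataclass(frozen=True)
class TargetWeight:
    """Accumulated weight of one protein target: ti = sum of mapped ci."""

    target_symbol: str
    ti: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_symbol", self.target_symbol.upper())
        if self.ti < 0:
            raise ValidationError(f"ti must be >= 0, got {self.ti}")


@dataclass(frozen=True)
class PathwayWeight:
    """Summed target weight of one gene set's scored members."""

    set_id: str
    p_weight: float


def normalize_ob(raw_ob: float, scale_hint: str = "auto") -> float:
    """Normalize an OB value to a probability in [0, 1].

    ``fraction`` passes through, ``percent`` divides by 100, ``auto``
    divides by 100 only when the value exceeds 1 (so 0.35 and 35 both map
    to 0.35, and exactly 1.0 stays a fraction).
    """
    if raw_ob < 0:
        raise ValidationError(f"OB must be >= 0, got {raw_ob}")
    if scale_hint == "fraction":
        if raw_ob > 1:
            raise ValidationError(f"fraction-scale OB must be <= 1, got {raw_ob}")
        return raw_ob
    if scale_hint == "percent":
        value = raw_ob / 100.0
    elif scale_hint == "auto":
        value = raw_ob / 100.0 if raw_ob > 1 else raw_ob
    else:
        raise ValueError(
            f"unknown scale_hint {scale_hint!r}; expected fraction, percent, or auto"
        )
    if value > 1:
        raise ValidationError(f"OB {raw_ob} exceeds 100 on the percent scale")
    return value


def read_ob_table(
    path: str | Path, scale_hint: str = "auto"
) -> list[ObRecord]:
    """Read a TSV/CSV OB table with header ``compound_id, ob``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        header = fh.readline()
        delim = "\t" if "\t" in header else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        names = [n.strip() for n in (reader.fieldnames or [])]
        for col in ("compound_id", "ob"):
            if col not in names:
                raise FormatError(f"{path}: missing required column {col!r}")
        records = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            row = {(k.strip() if k else k): v for k, v in row.items()}
            cid = (row["compound_id"] or "").strip()
            if cid in seen:
                raise ValidationError(f"{path}:{i}: duplicate compound_id {cid!r}")
            seen.add(cid)
            try:
                raw = float(row["ob"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{i}: non-numeric ob") from exc
            records.append(ObRecord(cid, normalize_ob(raw, scale_hint)))
    return records


def compute_component_weights(
    compounds: Sequence[Compound],
    ob_table: Iterable[ObRecord],
    missing_ob_policy: str | float = "error",
) -> list[ComponentWeight]:
    """Compute ``ci = rel_content_pct * ob`` for every compound.

    Parameters
    ----------
    missing_ob_policy:
        ``"error"`` raises when a compound has no OB record, ``"drop"``
        silently omits it, and a float value is used as the default OB.

    Returns weights sorted by descending ``ci``, ties broken by
    ``compound_id``, so output order is deterministic.
    """
    ob_by_id: dict[str, float] = {}
    for rec in ob_table:
        if rec.compound_id in ob_by_id:
            raise ValidationError(f"duplicate OB record for {rec.compound_id!r}")
        ob_by_id[rec.compound_id] = rec.ob

    weights: list[ComponentWeight] = []
    for comp in compounds:
        ob = ob_by_id.get(comp.compound_id)
        if ob is None:
            if missing_ob_policy == "error":
                raise ValidationError(
                    f"no OB record for compound {comp.compound_id!r}"
                )
            if missing_ob_policy == "drop":
                continue
            ob = normalize_ob(float(missing_ob_policy), "fraction")
        weights.append(ComponentWeight(comp.compound_id, comp.rel_content_pct * ob))
    weights.sort(key=lambda w: (-w.ci, w.compound_id))
    return weights


def aggregate_target_weights(
    weights: Sequence[ComponentWeight],
    mapping: "CompoundTargetMap",
    strict: bool = False,
) -> list[TargetWeight]:
    """Accumulate ``ti`` per target: the sum of ``ci`` over mapped compounds.

    Duplicate edges in the mapping count a compound once per target. In
    strict mode, mapping edges referencing a compound without a weight are
    an error; otherwise they contribute nothing.
    """
    ci_by_id = {w.compound_id: w.ci for w in weights}
    per_target: dict[str, set[str]] = {}
    for cid, target in mapping.edges:
        per_target.setdefault(target.upper(), set()).add(cid)

    out: list[TargetWeight] = []
    for target in sorted(per_target):
        total = 0.0
        for cid in sorted(per_target[target]):
            if cid not in ci_by_id:
                if strict:
                    raise ValidationError(
                        f"mapping references unknown compound {cid!r} "
                        f"(target {target})"
                    )
                continue
            total += ci_by_id[cid]
        out.append(TargetWeight(target, total))
    return out


def aggregate_pathway_weight(
    target_weights: Sequence[TargetWeight] | Mapping[str, float],
    member_targets: Iterable[str],
    set_id: str = "",
) -> PathwayWeight:
    """Sum ``ti`` over the scored members of a gene set.

    Members without a target weight contribute 0.
    """
    if isinstance(target_weights, Mapping):
        ti_by_symbol = {k.upper(): v for k, v in target_weights.items()}
    else:
        ti_by_symbol = {tw.target_symbol: tw.ti for tw in target_weights}
    total = sum(ti_by_symbol.get(m.upper(), 0.0) for m in set(member_targets))
    return PathwayWeight(set_id=set_id, p_weight=total)


def rerank_by_weight(rows: Sequence["EnrichmentRow"]) -> list["EnrichmentRow"]:
    """Re-order enrichment rows by descending pathway weight.

    Ties fall through to ascending p-value, then ``set_id``, so the order
    is a deterministic function of the inputs. ``rank_after`` is assigned
    1..m in the new order; ``rank_before`` is retained.
    """
    ordered = sorted(rows, key=lambda r: (-r.p_weight, r.p_value, r.set_id))
    return [replace(r, rank_after=i) for i, r in enumerate(ordered, start=1)]


def rank_shift_report(
    rows: Sequence["EnrichmentRow"],
) -> list[tuple[str, int, int, int]]:
    """Per-row ``(set_id, rank_before, rank_after, delta)`` records.

    ``delta = rank_before - rank_after``: positive means the weight
    re-ranking promoted the set. Sorted by descending delta, ties by
    ``set_id``.
    """
    records = []
    for r in rows:
        if r.rank_after is None:
            raise ValidationError(f"row {r.set_id!r} has no rank_after; rerank first")
        records.append((r.set_id, r.rank_before, r.rank_after, r.rank_before - r.rank_after))
    records.sort(key=lambda rec: (-rec[3], rec[0]))
    return records


def write_component_weights(
    weights: Sequence[ComponentWeight], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "ci"])
        for cw in weights:
            w.writerow([cw.compound_id, f"{cw.ci:.6g}"])


def write_target_weights(weights: Sequence[TargetWeight], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target_symbol", "ti"])
        for tw in weights:
            w.writerow([tw.target_symbol, f"{tw.ti:.6g}"])
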