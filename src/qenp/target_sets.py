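"""Gene-symbol target sets: loading, deduplication, and intersection.

Symbols are compared case-insensitively and stored upper-case so that
mixed-case exports from different databases collide as intended. No alias
or ortholog resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from qenp.errors import FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSet:
    """A labelled set of upper-case gene symbols."""

    label: str
    symbols: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        cleaned = frozenset(s.strip().upper() for s in self.symbols if s.strip())
        object.__setattr__(self, "symbols", cleaned)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def sorted(self) -> list[str]:
        return sorted(self.symbols)


def make_target_set(label: str, symbols: Iterable[str]) -> TargetSet:
    return TargetSet(label=label, symbols=frozenset(symbols))


def load_target_list(path: str | Path, label: str | None = None) -> TargetSet:
    """Load a one-symbol-per-line target list.

    Lines are trimmed, upper-cased, and deduplicated; blank lines are
    ignored. An empty file yields an empty set with a warning, not an
    error. Raw vs unique counts are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = [line.strip() for line in path.read_text().splitlines()]
    raw = [s for s in raw if s]
    ts = make_target_set(label if label is not None else path.stem, raw)
    if not raw:
        logger.warning("%s: empty target list", path)
    else:
        logger.info(
            "%s: %d raw symbols, %d unique after case-fold dedup",
            path, len(raw), len(ts),
        )
    return ts


def intersect_targets(drug: TargetSet, disease: TargetSet) -> TargetSet:
    """Exact set intersection; label records both provenances."""
    return TargetSet(
        label=f"{drug.label} ∩ {disease.label}",
        symbols=drug.symbols & disease.symbols,
    )


def write_target_list(ts: TargetSet, path: str | Path) -> None:
    """Write symbols one per line in sorted (deterministic) order."""
    Path(path).write_text("\n".join(ts.sorted()) + ("\n" if ts.symbols else ""))
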