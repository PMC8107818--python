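"""Seeded synthetic-data generators for offline pipeline testing.

Every generator derives its own random stream from ``(seed, generator
name)``, so adding a generator never perturbs the output of an existing
one and the same spec always reproduces byte-identical fixtures. Symbols
use a reserved ``T####`` namespace to avoid colliding with real gene
symbols in user data.

The headline construction is the *planted pathway*: one gene set whose
members are preferentially drawn from the targets of the
highest-content x highest-OB compounds, so that weight re-ranking should
promote it relative to its p-value rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from qenp.compound_table import Compound
from qenp.errors import ValidationError
from qenp.network_analysis import CompoundTargetMap, InteractionNetwork
from qenp.target_sets import TargetSet, make_target_set
from qenp.enrichment import GeneSet, GeneSetCollection
from qenp.weight_engine import ObRecord


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling a synthetic workspace; fully deterministic under seed."""

    seed: int = 0
    n_compounds: int = 19
    n_targets: int = 120
    n_disease_targets: int = 200
    overlap_fraction: float = 0.6
    n_sets: int = 20
    set_size_range: tuple[int, int] = (8, 25)
    content_concentration: float = 0.4  # Dirichlet concentration; lower = skewed
    ob_range: tuple[float, float] = (0.2, 0.9)
    planted_set_fraction: float = 0.9
    mean_out_degree: float = 6.0
    ob_content_correlated: bool = False

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must lie in [0, 1]")
        if not (0.0 <= self.planted_set_fraction <= 1.0):
            raise ValidationError("planted_set_fraction must lie in [0, 1]")
        lo, hi = self.ob_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("ob_range must be within [0, 1] with lo <= hi")


def _rng(spec_seed: int, name: str) -> np.random.Generator:
    # independent stream per generator: seed sequence keyed by name
    return np.random.default_rng(
        np.random.SeedSequence([spec_seed, int.from_bytes(name.encode(), "big") % (2**31)])
    )


PLANTED_SET_ID = "SET_PLANTED"


def gen_compound_table(spec: FixtureSpec) -> list[Compound]:
    """Synthetic composition table: Dirichlet contents scaled to 100.

    Contents sum to 100 within 1e-9; retention times strictly increase.
    Lower ``content_concentration`` skews mass onto fewer compounds
    (emulating a few dominant components plus a long tail).
    """
    rng = _rng(spec.seed, "compound_table")
    n = spec.n_compounds
    shares = rng.dirichlet(np.full(n, spec.content_concentration))
    # strictly increasing RTs in a plausible GC window
    gaps = rng.uniform(0.2, 1.2, size=n)
    rts = 4.0 + np.cumsum(gaps)
    return [
        Compound(
            compound_id=f"c{i + 1:02d}",
            name=f"synthetic-compound-{i + 1}",
            cas="",
            retention_time=float(rts[i]),
            rel_content_pct=float(shares[i] * 100.0),
        )
        for i in range(n)
    ]


def gen_ob_table(spec: FixtureSpec, compounds: list[Compound]) -> list[ObRecord]:
    """OB values uniform on ``ob_range``; optionally rank-correlated with content.

    With ``ob_content_correlated`` the highest-content compounds get the
    highest OB values, concentrating ci on the dominant compounds (used by
    the planted-pathway recovery simulation).
    """
    rng = _rng(spec.seed, "ob_table")
    lo, hi = spec.ob_range
    obs = rng.uniform(lo, hi, size=len(compounds))
    if spec.ob_content_correlated:
        content_order = np.argsort([-c.rel_content_pct for c in compounds])
        sorted_obs = np.sort(obs)[::-1]
        assigned = np.empty(len(compounds))
        assigned[content_order] = sorted_obs
        obs = assigned
    return [
        ObRecord(comp.compound_id, float(ob))
        for comp, ob in zip(compounds, obs)
    ]


def gen_target_universe(
    spec: FixtureSpec, compounds: list[Compound] | None = None
) -> tuple[CompoundTargetMap, TargetSet, GeneSetCollection, TargetSet]:
    """Bipartite map, disease set, gene-set collection, and universe.

    The disease set overlaps the compound-target pool by
    ``overlap_fraction``. One planted gene set draws
    ``planted_set_fraction`` of its members from targets of the
    top-content compounds; the remaining sets sample uniformly.
    """
    if compounds is None:
        compounds = gen_compound_table(spec)
    rng = _rng(spec.seed, "target_universe")
    symbols = [f"T{i + 1:04d}" for i in range(spec.n_targets)]

    # bipartite edges: per-compound out-degree ~ Poisson(mean_out_degree), >= 1
    edges: list[tuple[str, str]] = []
    targets_of: dict[str, list[str]] = {}
    for comp in compounds:
        deg = max(1, int(rng.poisson(spec.mean_out_degree)))
        deg = min(deg, spec.n_targets)
        chosen = rng.choice(spec.n_targets, size=deg, replace=False)
        targets_of[comp.compound_id] = [symbols[j] for j in sorted(chosen)]
        edges.extend((comp.compound_id, symbols[j]) for j in sorted(chosen))
    mapping = CompoundTargetMap(edges=tuple(edges))
    drug_targets = sorted(mapping.targets)

    # disease set: overlap_fraction of it comes from the drug-target pool,
    # the rest from disjoint disease-only symbols
    n_shared = round(spec.overlap_fraction * min(spec.n_disease_targets, len(drug_targets)))
    if n_shared > len(drug_targets):
        raise ValidationError(
            f"overlap_fraction {spec.overlap_fraction} demands {n_shared} shared "
            f"targets but only {len(drug_targets)} exist"
        )
    shared_idx = rng.choice(len(drug_targets), size=n_shared, replace=False)
    shared = [drug_targets[j] for j in sorted(shared_idx)]
    n_only = spec.n_disease_targets - n_shared
    disease_only = [f"D{i + 1:04d}" for i in range(n_only)]
    disease = make_target_set("disease", shared + disease_only)

    # gene sets over the drug-target universe; set 0 is planted on targets
    # of the top-content compounds
    by_content = sorted(compounds, key=lambda c: -c.rel_content_pct)
    top_pool: list[str] = []
    for comp in by_content[: max(1, len(compounds) // 4)]:
        top_pool.extend(targets_of[comp.compound_id])
    top_pool = sorted(set(top_pool))
    lo, hi = spec.set_size_range
    sets: list[GeneSet] = []
    for s in range(spec.n_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(drug_targets))
        if s == 0:
            intended_top = round(spec.planted_set_fraction * size)
            n_top = min(intended_top, len(top_pool))
            picked = [top_pool[j] for j in rng.choice(len(top_pool), size=n_top, replace=False)]
            rest_pool = [t for t in drug_targets if t not in set(picked)]
            # only the slice intended to be non-top is backfilled, so
            # planted_set_fraction=1 never dilutes the planted membership
            n_rest = min(size - intended_top, len(rest_pool))
            if n_rest > 0:
                picked += [rest_pool[j] for j in rng.choice(len(rest_pool), size=n_rest, replace=False)]
            sets.append(GeneSet(PLANTED_SET_ID, "planted pathway", frozenset(picked)))
        else:
            picked_idx = rng.choice(len(drug_targets), size=size, replace=False)
            sets.append(
                GeneSet(
                    f"SET_{s:03d}",
                    f"random set {s}",
                    frozenset(drug_targets[j] for j in picked_idx),
                )
            )
    collection = GeneSetCollection(sets=tuple(sets), namespace="pathway")
    universe = make_target_set("universe", drug_targets)
    return mapping, disease, collection, universe


def gen_ppi_edges(
    targets: TargetSet, density: float, seed: int
) -> InteractionNetwork:
    """Erdos-Renyi-style scored PPI over a target set.

    Each unordered pair is included independently with probability
    ``density``; scores are uniform on [0, 1]. Deterministic under seed.
    """
    if not (0.0 <= density <= 1.0):
        raise ValidationError("density must lie in [0, 1]")
    rng = _rng(seed, "ppi_edges")
    nodes = targets.sorted()
    edges: list[tuple[str, str, float | None]] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if density >= 1.0 or rng.random() < density:
                edges.append((nodes[i], nodes[j], float(rng.random())))
    return InteractionNetwork(nodes=frozenset(nodes), edges=tuple(edges))


def run_planted_replicate(
    seed: int, condition: str = "skewed"
) -> tuple[list, "object"]:
    """One end-to-end synthetic replicate of the weight re-ranking pipeline.

    ``condition="skewed"``: strongly concentrated content with OB rank-
    correlated to content, so the planted pathway should be promoted.
    ``condition="flat"``: every compound gets identical content and OB
    (ci all equal), removing the quantity-effect signal.
    ``condition="tiebreak"``: like flat, but every target weight is forced
    to 1 — pathway weight then reduces to the scored-member count, the
    tie-break-only baseline.

    Returns ``(all re-ranked rows, planted row)``.
    """
    from qenp.enrichment import enrich_and_rerank
    from qenp.target_sets import intersect_targets
    from qenp.weight_engine import aggregate_target_weights, compute_component_weights

    if condition not in ("skewed", "flat", "tiebreak"):
        raise ValueError(f"unknown condition {condition!r}")
    skewed = condition == "skewed"
    spec = FixtureSpec(
        seed=seed,
        planted_set_fraction=0.9,
        content_concentration=0.1 if skewed else 50.0,
        ob_content_correlated=skewed,
        overlap_fraction=0.8,
        n_targets=250,
    )
    structural = gen_compound_table(spec)
    if skewed:
        compounds = structural
        ob = gen_ob_table(spec, compounds)
    else:
        # flat quantity signal: equal content, constant OB
        compounds = [
            Compound(c.compound_id, c.name, "", c.retention_time,
                     100.0 / len(structural))
            for c in structural
        ]
        ob = [ObRecord(c.compound_id, 0.5) for c in compounds]
    mapping, disease, collection, universe = gen_target_universe(spec, structural)
    if condition == "tiebreak":
        tw: object = {t: 1.0 for t in mapping.targets}
    else:
        cw = compute_component_weights(compounds, ob)
        tw = aggregate_target_weights(cw, mapping)
    hits = intersect_targets(make_target_set("drug", mapping.targets), disease)
    rows = enrich_and_rerank(hits, tw, collection, universe, top_m=None,
                             min_size=1, max_size=500)
    planted = next(r for r in rows if r.set_id == PLANTED_SET_ID)
    return rows, planted


def write_workspace(spec: FixtureSpec, outdir: str | Path, ppi_density: float = 0.25) -> dict[str, Path]:
    """Emit a complete demo workspace in the TSV/GMT dialects the pipeline reads."""
    from qenp.compound_table import write_compound_table
    from qenp.enrichment import write_gmt
    from qenp.network_analysis import write_edge_list
    from qenp.target_sets import write_target_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds = gen_compound_table(spec)
    ob = gen_ob_table(spec, compounds)
    mapping, disease, collection, universe = gen_target_universe(spec, compounds)

    paths = {
        "compounds": outdir / "compounds.tsv",
        "ladder": outdir / "alkane_ladder.tsv",
        "ob": outdir / "ob.tsv",
        "target_map": outdir / "compound_targets.tsv",
        "disease": outdir / "disease_targets.txt",
        "gmt": outdir / "gene_sets.gmt",
        "universe": outdir / "universe.txt",
        "ppi": outdir / "ppi_edges.tsv",
    }
    write_compound_table(compounds, paths["compounds"])
    # ladder spanning all generated RTs (C8 upward, 2-minute rungs)
    max_rt = max(c.retention_time for c in compounds)
    n_rungs = min(int(max_rt / 2.0) + 2, 33)  # carbon numbers capped at C40
    rungs = [(8 + i, 2.0 + 2.0 * i) for i in range(n_rungs)]
    with open(paths["ladder"], "w") as fh:
        fh.write("carbon_number\tretention_time_min\n")
        for carbon, rt in rungs:
            fh.write(f"{carbon}\t{rt}\n")
    with open(paths["ob"], "w") as fh:
        fh.write("compound_id\tob\n")
        for rec in ob:
            fh.write(f"{rec.compound_id}\t{rec.ob:.6f}\n")
    with open(paths["target_map"], "w") as fh:
        fh.write("compound_id\ttarget_symbol\n")
        for cid, target in mapping.edges:
            fh.write(f"{cid}\t{target}\n")
    write_target_list(disease, paths["disease"])
    write_gmt(collection, paths["gmt"])
    write_target_list(universe, paths["universe"])
    ppi = gen_ppi_edges(universe, density=ppi_density, seed=spec.seed)
    write_edge_list(ppi, paths["ppi"])
    return paths
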