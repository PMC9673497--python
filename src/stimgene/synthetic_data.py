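"""Seeded synthetic benchmark generator.

Produces two classes of valid coding sequences with a configurable GC gap,
motifs planted at class-specific prevalences (amino-acid motifs via codon
choice, nucleotide motifs via synonymous-codon edits only), feature-linked
positive fold changes with an interferon-repressed tail in the negative
class, a preferential-attachment interaction graph with mixed edge
confidences, and smooth per-residue disorder scores.  Everything is
reproducible from the config seed, and a manifest records the planted
ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .io_curation import GeneRecord, write_fasta
from .pattern_mining import SlaapPattern, SlnPattern, pattern_present
from .sequence_features import CODON_FAMILIES, encode_nucleotide_features
from .protein_features import encode_protein_features

__all__ = ["BenchmarkConfig", "generate_cds", "generate_lfc", "generate_ppi",
           "generate_disorder", "make_benchmark"]

_SENSE_CODONS = tuple(
    c for aa, members in CODON_FAMILIES.items() if aa != "*" for c in members
)
_STOP_CODONS = CODON_FAMILIES["*"]
_AA_TO_CODONS = {aa: members for aa, members in CODON_FAMILIES.items() if aa != "*"}


@dataclass
class BenchmarkConfig:
    """Knobs of the synthetic benchmark; defaults give a desk-scale dataset."""

    n_pos: int = 300
    n_neg: int = 300
    n_elg: int = 20
    length_range: tuple[int, int] = (120, 220)  # codons including start/stop
    gc_pos: float = 0.52
    gc_neg: float = 0.55
    # Negative-class targets sit above the natural presence rate of these
    # patterns at the default lengths; planting only ever adds occurrences.
    # Both patterns are chosen to be reachable by synonymous codon swaps in
    # essentially every sequence (wobble-position flexibility).
    planted_slnps: list = field(
        default_factory=lambda: [("TT[CT]GA", 0.85, 0.40), ("ACGT[AG]", 0.80, 0.45)]
    )
    planted_slaaps: list = field(
        default_factory=lambda: [
            ("SxNxE", 0.152, 0.088), ("KEN", 0.45, 0.12), ("LxNL", 0.50, 0.15)
        ]
    )
    noise_features: int = 20
    lfc_weights: dict = field(
        default_factory=lambda: {"content_GC": -1.6, "mono_A": 1.2}
    )
    lfc_noise_sd: float = 0.6
    lfc_intercept_pos: float = 2.2
    lfc_intercept_neg: float = -0.4
    max_lfc: float = 12.6
    irg_fraction: float = 0.1
    irg_thresh: float = -0.871
    graph_nodes: int = 600
    graph_edges_per_node: int = 2
    edge_pass_fraction: float = 0.7
    unmapped_fraction: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range"] = list(self.length_range)
        return d


def _gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


def _codon_weights(gc_target: float) -> np.ndarray:
    """Sense-codon sampling weights w(c) ~ t^GC(c) hitting the GC target."""
    gc = np.array([_gc_count(c) for c in _SENSE_CODONS], dtype=float)

    def mean_gc(log_t: float) -> float:
        w = np.exp(log_t * gc)
        return float((w * gc).sum() / (3 * w.sum())) - gc_target

    log_t = brentq(mean_gc, -6, 6)
    w = np.exp(log_t * gc)
    return w / w.sum()


class PlantingError(RuntimeError):
    """Raised when a motif cannot be planted without breaking CDS validity."""


def _plant_slaap(codons: list[str], pattern: SlaapPattern, rng) -> list[str]:
    """Overwrite a random interior stretch so the protein matches the pattern."""
    width = pattern.span
    if len(codons) - 2 < width:
        raise PlantingError("sequence too short for amino-acid motif")
    start = int(rng.integers(1, len(codons) - 1 - width))
    offsets = set(pattern.offsets)
    fixed = dict(zip(pattern.offsets, pattern.fixed))
    out = list(codons)
    for k in range(width):
        if k in offsets:
            choices = _AA_TO_CODONS[fixed[k]]
            out[start + k] = choices[int(rng.integers(len(choices)))]
        # wildcard positions keep the existing sense codon
    return out


_CODON_TO_AA = {c: aa for aa, members in _AA_TO_CODONS.items() for c in members}


def _plant_slnp(codons: list[str], pattern: SlnPattern, rng) -> list[str]:
    """Create a nucleotide-motif match using synonymous codon swaps only.

    Scans interior 3-codon windows in random order and replaces them with a
    synonymous combination whose 9-nt concatenation contains a match.
    """
    width = len(pattern)
    slots = np.arange(1, len(codons) - 3)  # window (j, j+1, j+2), all interior
    rng.shuffle(slots)
    for j in slots:
        j = int(j)
        alternatives = [
            _AA_TO_CODONS[_CODON_TO_AA[codons[j + k]]] for k in range(3)
        ]
        hits = []
        for combo in product(*alternatives):
            window = "".join(combo)
            for off in range(0, 9 - width + 1):
                segment = window[off : off + width]
                if all(b in s for b, s in zip(segment, pattern.positions)):
                    hits.append(combo)
                    break
        if hits:
            combo = hits[int(rng.integers(len(hits)))]
            out = list(codons)
            out[j : j + 3] = combo
            return out
    raise PlantingError(f"could not plant {pattern.text} by synonymous edits")


def _random_codons(n_internal: int, weights: np.ndarray, rng) -> list[str]:
    idx = rng.choice(len(_SENSE_CODONS), size=n_internal, p=weights)
    return ["ATG"] + [_SENSE_CODONS[i] for i in idx] + [
        _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
    ]


def _plant_to_prevalence(
    codon_lists: list[list[str]], pattern, prevalence: float, rng, on_protein: bool
) -> None:
    """Plant a motif into random non-containing sequences up to the target count."""
    def seq_of(codons):
        joined = "".join(codons)
        if on_protein:
            from .protein_features import translate

            return translate(joined)
        return joined

    present = [bool(pattern_present(pattern, seq_of(c))) for c in codon_lists]
    target = round(prevalence * len(codon_lists))
    deficit = target - sum(present)
    if deficit <= 0:
        return
    candidates = np.array([i for i, p in enumerate(present) if not p])
    rng.shuffle(candidates)
    planted = 0
    for i in candidates:
        if planted >= deficit:
            break
        i = int(i)
        try:
            if on_protein:
                codon_lists[i] = _plant_slaap(codon_lists[i], pattern, rng)
            else:
                codon_lists[i] = _plant_slnp(codon_lists[i], pattern, rng)
            planted += 1
        except PlantingError:
            continue  # this sequence has no compatible slot; try another
    if planted < deficit:
        raise PlantingError(
            f"target prevalence {prevalence} for {pattern.text} unreachable: "
            f"planted {planted} of {deficit} needed"
        )


def generate_cds(config: BenchmarkConfig, rng=None):
    """Generate the labelled sequence classes.

    Returns ``(records, planted)`` where records is a list of
    :class:`GeneRecord` with cds/protein filled and planted is the parsed
    planted-pattern list for the manifest.
    """
    from .protein_features import translate

    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.length_range
    slnps = [(SlnPattern.parse(t), pp, pn) for t, pp, pn in config.planted_slnps]
    slaaps = [(SlaapPattern.parse(t), pp, pn) for t, pp, pn in config.planted_slaaps]

    records: list[GeneRecord] = []
    class_plan = [
        ("ISG", config.n_pos, config.gc_pos, 1),
        ("nonISG", config.n_neg, config.gc_neg, 2),
        ("ELG", config.n_elg, config.gc_neg, 2),
    ]
    for label, count, gc_target, prevalence_col in class_plan:
        if count == 0:
            continue
        weights = _codon_weights(gc_target)
        codon_lists = [
            _random_codons(int(rng.integers(lo, hi + 1)) - 2, weights, rng)
            for _ in range(count)
        ]
        if label != "ELG":
            for pattern, prev_pos, prev_neg in slnps:
                prev = prev_pos if label == "ISG" else prev_neg
                _plant_to_prevalence(codon_lists, pattern, prev, rng, on_protein=False)
            for pattern, prev_pos, prev_neg in slaaps:
                prev = prev_pos if label == "ISG" else prev_neg
                _plant_to_prevalence(codon_lists, pattern, prev, rng, on_protein=True)
        for i, codons in enumerate(codon_lists):
            cds = "".join(codons)
            records.append(
                GeneRecord(
                    gene_id=f"{label}_{i:04d}",
                    label=label,
                    cds=cds,
                    protein=translate(cds),
                )
            )
    return records, {"slnps": config.planted_slnps, "slaaps": config.planted_slaaps}


def generate_lfc(records, config: BenchmarkConfig, rng) -> None:
    """Assign feature-linked log2 fold changes in place.

    Positive-class values are an affine combination of min-max-normalized
    features plus Gaussian noise, clipped to (0, max_lfc]; the negative
    class uses the same feature weights around a lower intercept, with a
    configured fraction pushed below the repression threshold.  ELG records
    get no fold change.
    """
    scored = [r for r in records if r.label != "ELG"]
    raw = {name: np.empty(len(scored)) for name in config.lfc_weights}
    for row, rec in enumerate(scored):
        feats = encode_nucleotide_features(rec.cds)
        feats.update(encode_protein_features(rec.protein))
        for name in config.lfc_weights:
            raw[name][row] = feats[name]
    combo = np.zeros(len(scored))
    for name, weight in config.lfc_weights.items():
        values = raw[name]
        span = values.max() - values.min()
        norm = (values - values.min()) / span if span > 0 else np.zeros_like(values)
        combo += weight * norm
    noise = rng.normal(0, config.lfc_noise_sd, size=len(scored))
    for row, rec in enumerate(scored):
        intercept = (
            config.lfc_intercept_pos if rec.label == "ISG" else config.lfc_intercept_neg
        )
        value = intercept + combo[row] + noise[row]
        if rec.label == "ISG":
            value = min(max(value, 1e-3), config.max_lfc)
        rec.log2fc = float(value)
        rec.fdr = float(rng.uniform(1e-6, 0.01 if rec.label == "ISG" else 1.0))
    negatives = [r for r in scored if r.label == "nonISG"]
    n_irg = round(config.irg_fraction * len(negatives))
    if n_irg:
        chosen = rng.choice(len(negatives), size=n_irg, replace=False)
        for k in chosen:
            negatives[int(k)].log2fc = float(
                config.irg_thresh - rng.uniform(0.05, 1.5)
            )


def generate_ppi(config: BenchmarkConfig, gene_ids, rng):
    """Preferential-attachment graph, scored edges and a partial gene map."""
    graph = nx.barabasi_albert_graph(
        config.graph_nodes, config.graph_edges_per_node,
        seed=int(rng.integers(2**31)),
    )
    rename = {i: f"P{i:05d}" for i in graph.nodes}
    edges = []
    for a, b in graph.edges:
        if rng.random() < config.edge_pass_fraction:
            conf = float(rng.uniform(0.6301, 0.99))
        else:
            conf = float(rng.uniform(0.1, 0.63))
        edges.append((rename[a], rename[b], round(conf, 4)))
    proteins = list(rename.values())
    mapping = {}
    for gid in gene_ids:
        if rng.random() >= config.unmapped_fraction:
            mapping[gid] = proteins[int(rng.integers(len(proteins)))]
    return edges, mapping


def generate_disorder(length: int, rng) -> list[float]:
    """Smooth autocorrelated scores in [0,1] so runs of varied length exist."""
    steps = rng.normal(0, 0.35, size=length)
    x = np.empty(length)
    x[0] = rng.normal(0, 1)
    for i in range(1, length):
        x[i] = 0.92 * x[i - 1] + steps[i]
    return [float(v) for v in np.round(1 / (1 + np.exp(-x)), 4)]


def make_benchmark(config: BenchmarkConfig, out_dir) -> Path:
    """Write the full input-file set plus a ground-truth manifest.

    Files: cds.fasta, protein.fasta, annotation.tsv, fold_changes.tsv,
    ppi_edges.tsv, gene_protein_map.tsv, disorder.tsv, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    records, planted = generate_cds(config, rng)
    generate_lfc(records, config, rng)

    for rec in records:
        rec.n_transcripts = 1 + int(rng.poisson(2))
        rec.n_orfs = 1 + int(rng.poisson(1))
        rec.n_coding_exons = 1 + int(rng.poisson(5))
        rec.n_paralogues = int(rng.negative_binomial(2, 0.25))
        rec.ds = float(np.round(rng.gamma(4, 8), 4))
        rec.dn = float(np.round(rec.ds * rng.beta(2, 30), 4))
        rec.dnds = float(np.round(rec.dn / rec.ds, 6)) if rec.ds else None

    write_fasta([(r.gene_id, r.cds) for r in records], out / "cds.fasta")
    write_fasta([(r.gene_id, r.protein) for r in records], out / "protein.fasta")

    from .io_curation import write_annotation_table

    write_annotation_table(records, out / "annotation.tsv")

    with open(out / "fold_changes.tsv", "w") as fh:
        fh.write("gene_id\tifn_type\tlog2fc\tcontext\n")
        for rec in records:
            if rec.log2fc is None:
                continue
            fh.write(f"{rec.gene_id}\tI\t{rec.log2fc:.4f}\tfibroblast\n")
            for extra in range(int(rng.integers(0, 3))):
                fc = rec.log2fc + float(rng.normal(0, 0.4))
                fh.write(f"{rec.gene_id}\tI\t{fc:.4f}\tcontext_{extra}\n")

    edges, mapping = generate_ppi(config, [r.gene_id for r in records], rng)
    with open(out / "ppi_edges.tsv", "w") as fh:
        fh.write("id_a\tid_b\tconfidence\n")
        for a, b, conf in edges:
            fh.write(f"{a}\t{b}\t{conf}\n")
    with open(out / "gene_protein_map.tsv", "w") as fh:
        fh.write("gene_id\tprotein_id\n")
        for gid, pid in mapping.items():
            fh.write(f"{gid}\t{pid}\n")

    with open(out / "disorder.tsv", "w") as fh:
        fh.write("protein_id\tposition\tscore\n")
        for rec in records:
            for pos, score in enumerate(generate_disorder(len(rec.protein), rng), 1):
                fh.write(f"{rec.gene_id}\t{pos}\t{score}\n")

    manifest = {
        "config": config.to_dict(),
        "planted": planted,
        "lfc_weights": config.lfc_weights,
        "irg_thresh": config.irg_thresh,
        "n_records": len(records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
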