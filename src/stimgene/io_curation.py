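"""Reading, writing and curation of gene records.

This module owns all external text formats (FASTA, TSV tables), coding
sequence validation, and the fold-change-based label refinement rules used
to split genes into high-confidence stimulated / unstimulated sets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GeneRecord",
    "FoldChangeObservation",
    "CdsValidity",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "validate_cds",
    "refine_labels",
    "tag_irg",
    "read_annotation_table",
    "read_fold_change_table",
    "write_refined_labels",
]

_NUCS = frozenset("ACGTN")
_STOPS = frozenset({"TAA", "TAG", "TGA"})


class FastaParseError(ValueError):
    """Raised when a FASTA file violates basic record syntax."""


@dataclass
class GeneRecord:
    """One gene: identifiers, labels, expression response and sequences.

    ``label`` is the primary-experiment class (``ISG``, ``nonISG`` or
    ``ELG``); ``refined_label`` is assigned by :func:`refine_labels`.
    ``log2fc`` and ``fdr`` come from the primary type-I interferon
    experiment and are ``None`` for low-expression (ELG) genes.
    """

    gene_id: str
    label: str = "nonISG"
    log2fc: float | None = None
    fdr: float | None = None
    cds: str = ""
    protein: str = ""
    n_transcripts: int = 0
    n_orfs: int = 0
    n_coding_exons: int = 0
    n_paralogues: int = 0
    dn: float | None = None
    ds: float | None = None
    dnds: float | None = None
    refined_label: str | None = None
    irg: bool = False


@dataclass(frozen=True)
class FoldChangeObservation:
    """One fold-change measurement for a gene in some interferon context."""

    gene_id: str
    ifn_type: str  # "I", "II" or "III"
    log2fc: float
    context: str = ""

    def __post_init__(self) -> None:
        if self.ifn_type not in {"I", "II", "III"}:
            raise ValueError(f"unknown interferon type: {self.ifn_type!r}")


@dataclass(frozen=True)
class CdsValidity:
    """Flag report from :func:`validate_cds`."""

    bad_length: bool = False
    bad_start: bool = False
    bad_stop: bool = False
    internal_stop: bool = False
    ambiguous_bases: bool = False

    @property
    def ok(self) -> bool:
        return not (
            self.bad_length
            or self.bad_start
            or self.bad_stop
            or self.internal_stop
            or self.ambiguous_bases
        )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are upper-cased and ids are the first whitespace-delimited
    token of the header line.  A malformed record raises
    :class:`FastaParseError` naming the offending line.

    A tiny parser is used instead of Biopython's so that syntax errors can
    be reported with line numbers; the format handled here is plain
    multi-line FASTA only.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                token = line[1:].split()
                if not token:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                header = token[0]
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line.upper())
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def validate_cds(sequence: str) -> CdsValidity:
    """Validate a coding sequence and report individual problem flags.

    Characters outside ``{A,C,G,T,N}`` (after upper-casing) raise
    ``ValueError``; everything else is reported via flags so callers can
    decide between strict and permissive handling.
    """
    if not sequence:
        raise ValueError("empty coding sequence")
    seq = sequence.upper()
    bad = set(seq) - _NUCS
    if bad:
        raise ValueError(f"non-nucleotide characters in CDS: {sorted(bad)}")
    bad_length = len(seq) % 3 != 0
    bad_start = not seq.startswith("ATG")
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    bad_stop = not codons or codons[-1] not in _STOPS
    # a premature stop is only "internal" when a proper terminus exists;
    # otherwise the defect is already captured by bad_stop
    internal_stop = not bad_stop and any(c in _STOPS for c in codons[:-1])
    return CdsValidity(
        bad_length=bad_length,
        bad_start=bad_start,
        bad_stop=bad_stop,
        internal_stop=internal_stop,
        ambiguous_bases="N" in seq,
    )


def refine_labels(
    records: Sequence[GeneRecord],
    observations: Sequence[FoldChangeObservation],
    up_thresh: float = 1.0,
    down_thresh: float = -1.0,
    nonisg_thresh: float = 0.0,
) -> dict[str, str]:
    """Assign a refined label to every gene from type-I IFN observations.

    An ISG is kept as ``ISG_high`` iff at least one type-I observation shows
    log2fc strictly above ``up_thresh`` and none falls strictly below
    ``down_thresh``; otherwise it becomes ``ISG_low``.  A non-ISG survives
    as ``nonISG_high`` iff no type-I observation exceeds ``nonisg_thresh``;
    otherwise it is ``excluded``.  ELG records pass through unchanged.  All
    comparisons are strict, so boundary values fail the high-confidence
    tests.
    """
    labelled = {r.gene_id: r for r in records}
    by_gene: dict[str, list[float]] = {}
    for obs in observations:
        if obs.gene_id not in labelled:
            raise ValueError(
                f"observation for gene {obs.gene_id!r} without a primary label"
            )
        if obs.ifn_type == "I":
            by_gene.setdefault(obs.gene_id, []).append(obs.log2fc)

    refined: dict[str, str] = {}
    for rec in records:
        obs_fc = by_gene.get(rec.gene_id, [])
        if rec.label == "ELG":
            refined[rec.gene_id] = "ELG"
        elif rec.label == "ISG":
            up = any(fc > up_thresh for fc in obs_fc)
            down = any(fc < down_thresh for fc in obs_fc)
            refined[rec.gene_id] = "ISG_high" if up and not down else "ISG_low"
        elif rec.label == "nonISG":
            enhanced = any(fc > nonisg_thresh for fc in obs_fc)
            refined[rec.gene_id] = "excluded" if enhanced else "nonISG_high"
        else:
            raise ValueError(f"unknown primary label {rec.label!r}")
        rec.refined_label = refined[rec.gene_id]
    return refined


def tag_irg(records: Sequence[GeneRecord], irg_thresh: float = -0.871) -> dict[str, bool]:
    """Flag the downregulated (interferon-repressed) subset of non-ISGs.

    True iff the primary label is ``nonISG`` and the primary-experiment
    log2 fold change is strictly below ``irg_thresh``.  The default
    threshold is configurable; it is an offered convention, not a fixed rule.
    """
    flags: dict[str, bool] = {}
    for rec in records:
        flag = (
            rec.label == "nonISG"
            and rec.log2fc is not None
            and rec.log2fc < irg_thresh
        )
        rec.irg = flag
        flags[rec.gene_id] = flag
    return flags


# --- tabular I/O -----------------------------------------------------------

_ANNOT_INT_COLS = ("n_transcripts", "n_orfs", "n_coding_exons", "n_paralogues")
_ANNOT_FLOAT_COLS = ("log2fc", "fdr", "dn", "ds", "dnds")


def read_annotation_table(path) -> list[GeneRecord]:
    """Read a TSV annotation table (header row, columns named as fields)."""
    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            kwargs: dict = {"gene_id": row["gene_id"], "label": row["label"]}
            for col in _ANNOT_FLOAT_COLS:
                val = row.get(col, "")
                kwargs[col] = float(val) if val not in ("", "NA", None) else None
            for col in _ANNOT_INT_COLS:
                val = row.get(col, "")
                kwargs[col] = int(val) if val not in ("", "NA", None) else 0
            records.append(GeneRecord(**kwargs))
    return records


def write_annotation_table(records: Sequence[GeneRecord], path) -> None:
    cols = ["gene_id", "label"] + list(_ANNOT_FLOAT_COLS) + list(_ANNOT_INT_COLS)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(cols)
        for rec in records:
            writer.writerow(
                ["" if (v := getattr(rec, c)) is None else v for c in cols]
            )


def read_fold_change_table(path) -> list[FoldChangeObservation]:
    """Read a TSV of fold-change observations (gene_id, ifn_type, log2fc, context)."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                FoldChangeObservation(
                    gene_id=row["gene_id"],
                    ifn_type=row["ifn_type"],
                    log2fc=float(row["log2fc"]),
                    context=row.get("context", ""),
                )
            )
    return out


def write_refined_labels(records: Sequence[GeneRecord], path) -> None:
    """Emit the refined labels as TSV (gene_id, refined_label, irg_flag)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "refined_label", "irg_flag"])
        for rec in records:
            writer.writerow([rec.gene_id, rec.refined_label or "", int(rec.irg)])
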