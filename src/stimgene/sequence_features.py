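"""Nucleotide-level feature encoders for coding sequences.

Encodes single-base composition, the six paired-base contents, overlapping
dinucleotide and 4-mer compositions, and within-synonymous-family codon
usage.  Positions or windows containing ambiguous bases (``N``) are
excluded from both numerator and denominator.
"""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "BASES",
    "PAIRS",
    "DINUCS",
    "FOURMERS",
    "CODONS",
    "CODON_FAMILIES",
    "mono_composition",
    "paired_content",
    "dinuc_composition",
    "fourmer_composition",
    "codon_usage",
    "encode_nucleotide_features",
    "nucleotide_feature_names",
]

BASES = "ACGT"
PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")
DINUCS = tuple(a + b for a, b in product(BASES, repeat=2))
FOURMERS = tuple("".join(p) for p in product(BASES, repeat=4))
CODONS = tuple("".join(p) for p in product("TCAG", repeat=3))

# codon -> amino acid, stop codons grouped as one family "*"
_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

CODON_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in CODONS:
    CODON_FAMILIES.setdefault(_CODON_TO_AA[_codon], tuple())
CODON_FAMILIES = {
    aa: tuple(c for c in CODONS if _CODON_TO_AA[c] == aa) for aa in CODON_FAMILIES
}


def _clean(cds: str) -> str:
    seq = cds.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return seq


def mono_composition(cds: str) -> dict[str, float]:
    """Fraction of each unambiguous base among unambiguous positions."""
    seq = _clean(cds)
    counts = {b: seq.count(b) for b in BASES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return {b: counts[b] / total for b in BASES}


def paired_content(cds: str, pair: str) -> float:
    """Combined content of two bases, e.g. GC content for pair='CG'."""
    key = "".join(sorted(pair.upper()))
    if key not in PAIRS:
        raise ValueError(f"unknown base pair {pair!r}")
    mono = mono_composition(cds)
    return mono[key[0]] + mono[key[1]]


def _window_composition(
    cds: str, k: int, kmers: tuple[str, ...], min_windows: int = 1
) -> dict[str, float]:
    seq = _clean(cds)
    if len(seq) < k:
        raise ValueError(f"sequence shorter than window width {k}")
    counts = dict.fromkeys(kmers, 0)
    retained = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        counts[window] += 1
        retained += 1
    if retained < min_windows:
        raise ValueError(f"fewer than {min_windows} unambiguous windows")
    return {w: c / retained for w, c in counts.items()}


def dinuc_composition(cds: str) -> dict[str, float]:
    """Overlapping 5'->3' dinucleotide fractions (16 values)."""
    return _window_composition(cds, 2, DINUCS, min_windows=2)


def fourmer_composition(cds: str) -> dict[str, float]:
    """Overlapping 4-mer fractions (256 values)."""
    return _window_composition(cds, 4, FOURMERS, min_windows=1)


def codon_usage(cds: str, strict: bool = False) -> dict[str, float]:
    """Relative usage of each codon within its synonymous family.

    Codons are read in frame from position 0.  The three stop codons form a
    single family.  A family absent from the CDS contributes zeros for all
    of its members.  ``N``-containing codons are skipped.
    """
    seq = _clean(cds)
    if len(seq) % 3 != 0:
        if strict:
            raise ValueError("CDS length is not a multiple of 3")
        seq = seq[: len(seq) - len(seq) % 3]
    counts = dict.fromkeys(CODONS, 0)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" not in codon:
            counts[codon] += 1
    usage = {}
    for members in CODON_FAMILIES.values():
        family_total = sum(counts[c] for c in members)
        for c in members:
            usage[c] = counts[c] / family_total if family_total else 0.0
    return {c: usage[c] for c in CODONS}


def encode_nucleotide_features(cds: str) -> dict[str, float]:
    """All nucleotide features of one CDS as a flat named dict.

    Names: ``mono_A``, ``content_GC``, ``dinuc_CpG``, ``k4_CGCG``,
    ``codon_AGA``.  Paired contents are named with the conventional base
    order (``GC`` not ``CG``, ``GT`` etc. as stored in :data:`PAIRS` but
    ``CG`` is reported as ``GC``).
    """
    out: dict[str, float] = {}
    mono = mono_composition(cds)
    for b in BASES:
        out[f"mono_{b}"] = mono[b]
    for pair in PAIRS:
        name = "GC" if pair == "CG" else pair
        out[f"content_{name}"] = mono[pair[0]] + mono[pair[1]]
    dinuc = dinuc_composition(cds)
    for d in DINUCS:
        out[f"dinuc_{d[0]}p{d[1]}"] = dinuc[d]
    fourmer = fourmer_composition(cds)
    for w in FOURMERS:
        out[f"k4_{w}"] = fourmer[w]
    usage = codon_usage(cds)
    for c in CODONS:
        out[f"codon_{c}"] = usage[c]
    return out


def nucleotide_feature_names() -> list[str]:
    """Manifest of the 346 nucleotide feature column names, in output order."""
    names = [f"mono_{b}" for b in BASES]
    names += [f"content_{'GC' if p == 'CG' else p}" for p in PAIRS]
    names += [f"dinuc_{d[0]}p{d[1]}" for d in DINUCS]
    names += [f"k4_{w}" for w in FOURMERS]
    names += [f"codon_{c}" for c in CODONS]
    return names
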