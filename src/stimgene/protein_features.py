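"""Protein-level feature encoders: translation, amino-acid and group compositions."""

from __future__ import annotations

from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "GROUP_SCHEME",
    "translate",
    "aa_composition",
    "group_composition",
    "encode_protein_features",
    "protein_feature_names",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_CHARGED = set("RHKDE")

#: The 17 physicochemical / geometric residue groups.
GROUP_SCHEME: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AGILPV"),
    "aromatic_huge": frozenset("FWY"),
    "sulphur": frozenset("CM"),
    "hydroxyl": frozenset("ST"),
    "acidic_negative": frozenset("DE"),
    "amide": frozenset("NQ"),
    "positive_charged": frozenset("RHK"),
    "hydrophobic": frozenset("ACILMFVW"),
    "neutral": frozenset("GHPSTY"),
    "hydrophilic": frozenset("RNDQEK"),
    "tiny": frozenset("GAS"),
    "small": frozenset("NDCPT"),
    "medium": frozenset("QEHV"),
    "large": frozenset("RILKM"),
    "uncharged": frozenset(set(AMINO_ACIDS) - _CHARGED),
    "polar": frozenset("RHKDENQSTY"),
    "nonpolar": frozenset(set(AMINO_ACIDS) - set("RHKDENQSTY")),
}


def translate(cds: str, strict: bool = True) -> str:
    """Translate a CDS with the standard genetic code, dropping the terminal stop.

    In strict mode an internal stop codon or a frame violation raises
    ``ValueError``; otherwise translation stops at the first stop codon.
    """
    seq = cds.upper()
    if len(seq) % 3 != 0:
        if strict:
            raise ValueError("CDS length is not a multiple of 3")
        seq = seq[: len(seq) - len(seq) % 3]
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        if strict:
            raise ValueError("internal stop codon")
        protein = protein.split("*", 1)[0]
    return protein


def aa_composition(protein: str) -> dict[str, float]:
    """Fractions of the 20 standard residues, excluding non-standard ones."""
    seq = protein.upper()
    counts = {aa: seq.count(aa) for aa in AMINO_ACIDS}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("protein contains no standard residues")
    return {aa: counts[aa] / total for aa in AMINO_ACIDS}


def group_composition(
    protein: str, scheme: dict[str, frozenset[str]] | None = None
) -> dict[str, float]:
    """Group fractions: each group's value is the sum of its members' fractions."""
    scheme = GROUP_SCHEME if scheme is None else scheme
    comp = aa_composition(protein)
    return {
        name: sum(comp[aa] for aa in members) for name, members in scheme.items()
    }


def encode_protein_features(protein: str) -> dict[str, float]:
    """All protein features as a flat named dict (``aa_A`` ... ``grp_polar``)."""
    out = {f"aa_{aa}": v for aa, v in aa_composition(protein).items()}
    out.update({f"grp_{name}": v for name, v in group_composition(protein).items()})
    return out


def protein_feature_names() -> list[str]:
    """Manifest of the 37 protein feature column names, in output order."""
    return [f"aa_{aa}" for aa in AMINO_ACIDS] + [f"grp_{g}" for g in GROUP_SCHEME]
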