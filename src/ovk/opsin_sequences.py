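"""Opsin sequence handling in the bovine-rhodopsin coordinate frame.

Vertebrate visual opsins are conventionally numbered against bovine
rhodopsin (348 residues), so that a substitution such as S299A names the
same structural site in any opsin regardless of indels elsewhere in the
protein.  This module reads opsin sequences, translates coding sequence,
aligns query opsins pairwise against references and against bovine
rhodopsin, and reports substitutions in bovine site numbering.

Pairwise global alignment (Needleman-Wunsch, BLOSUM62, affine gaps
open 10 / extend 1) stands in for a multiple alignment: opsins within a
class are typically >85% identical, where pairwise and multiple
alignments assign the same site homology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

OPSIN_CLASSES = ("RH1", "SWS1", "SWS2", "RH2", "LWS")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_STOP_CODONS = set(standard_dna_table.stop_codons)

BOVINE_LENGTH = 348


def bovine_rhodopsin() -> str:
    """Return the 348-residue bovine rhodopsin reference sequence."""
    with resources.files("ovk.data").joinpath("bovine_rhodopsin.fasta").open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return str(rec.seq)


def default_tm_ranges() -> list[tuple[int, int]]:
    """Transmembrane helix ranges (1-based, inclusive) in bovine numbering."""
    with resources.files("ovk.data").joinpath("tm_ranges.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return [tuple(r) for r in cfg["tm_ranges"]]


@dataclass
class OpsinSequence:
    """An opsin identified by class, with amino acids and optional CDS."""

    id: str
    opsin_class: str
    amino_acids: str
    nucleotide_cds: Optional[str] = None

    def __post_init__(self) -> None:
        if self.opsin_class not in OPSIN_CLASSES:
            raise ValueError(
                f"unknown opsin class {self.opsin_class!r}; expected one of {OPSIN_CLASSES}"
            )
        if not self.amino_acids:
            raise ValueError("amino_acids must be non-empty")
        if "-" in self.amino_acids:
            raise ValueError("amino_acids must not contain gap characters")
        bad = set(self.amino_acids) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"non-standard residue letters: {sorted(bad)}")
        if self.nucleotide_cds is not None:
            if translate_cds(self.nucleotide_cds) != self.amino_acids:
                raise ValueError("nucleotide_cds translation does not match amino_acids")


@dataclass(frozen=True, order=True)
class Substitution:
    """A residue difference at a bovine-numbered site (reference -> query)."""

    bovine_site: int
    from_residue: str
    to_residue: str

    def __post_init__(self) -> None:
        if self.from_residue == self.to_residue:
            raise ValueError("from_residue must differ from to_residue")

    def __str__(self) -> str:  # e.g. "S299A"
        return f"{self.from_residue}{self.bovine_site}{self.to_residue}"


@dataclass
class NumberedAlignment:
    """Pairwise alignment columns with optional bovine site numbers.

    Each column is (query residue or None, reference residue or None,
    bovine site or None).  bovine_site is set only when the reference is
    bovine rhodopsin and the column contains a bovine residue.
    """

    query_id: str
    reference_id: str
    columns: list[tuple[Optional[str], Optional[str], Optional[int]]]
    low_coverage: bool = False

    def site_map(self) -> dict[int, str]:
        """Map bovine site -> query residue (sites where query has a residue)."""
        return {
            site: q
            for q, _r, site in self.columns
            if site is not None and q is not None
        }

    def query_index_of_site(self, site: int) -> Optional[int]:
        """0-based index in the ungapped query of the bovine site, or None."""
        idx = 0
        for q, _r, s in self.columns:
            if q is not None:
                if s == site:
                    return idx
                idx += 1
            elif s == site:
                return None
        return None


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    A trailing stop codon is trimmed silently; an internal stop is an
    error naming the offending codon index (0-based).  Codons containing
    N translate to 'X' unless all resolutions agree on one residue.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGTN"):
        raise ValueError("CDS contains characters outside {A,C,G,T,N}")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOP_CODONS:
        codons = codons[:-1]
    out = []
    for i, codon in enumerate(codons):
        if "N" in codon:
            if codon.count("N") == 1:
                residues = {str(Seq(codon.replace("N", b)).translate(table=1)) for b in "ACGT"}
                if len(residues) == 1 and "*" not in residues:
                    out.append(residues.pop())
                    continue
            out.append("X")
            continue
        aa = str(Seq(codon).translate(table=1))
        if aa == "*":
            raise ValueError(f"internal stop codon at codon index {i}")
        out.append(aa)
    return "".join(out)


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def align_pair(query: str, reference: str,
               query_id: str = "query", reference_id: str = "reference") -> NumberedAlignment:
    """Global pairwise alignment of two amino-acid sequences.

    Maximal BLOSUM62 score under affine gaps (open 10, extend 1); ties
    broken deterministically by taking the first optimal alignment in
    the aligner's canonical ordering.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    for name, s in (("query", query), ("reference", reference)):
        bad = set(s) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"{name} contains non-standard letters: {sorted(bad)}")
    aln = _aligner().align(query, reference)[0]
    q_gapped, r_gapped = str(aln[0]), str(aln[1])
    columns = [
        (q if q != "-" else None, r if r != "-" else None, None)
        for q, r in zip(q_gapped, r_gapped)
    ]
    return NumberedAlignment(query_id, reference_id, columns)


def assign_bovine_numbering(query: OpsinSequence, bovine: Optional[str] = None) -> NumberedAlignment:
    """Align a query opsin to bovine rhodopsin and number its residues.

    Every column holding a bovine residue carries that residue's 1-based
    bovine position; query residues inherit the site of their column.
    If fewer than half the bovine residues align to query residues the
    result is flagged low-coverage (likely not an opsin).
    """
    if bovine is None:
        bovine = bovine_rhodopsin()
    if len(bovine) != BOVINE_LENGTH:
        raise ValueError(f"expected the {BOVINE_LENGTH}-residue bovine rhodopsin sequence")
    aln = align_pair(query.amino_acids, bovine, query.id, "bovine_rhodopsin")
    site = 0
    numbered = []
    covered = 0
    for q, r, _ in aln.columns:
        s = None
        if r is not None:
            site += 1
            s = site
            if q is not None:
                covered += 1
        numbered.append((q, r, s))
    aln.columns = numbered
    aln.low_coverage = covered < 0.5 * BOVINE_LENGTH
    if aln.low_coverage:
        warnings.warn(
            f"{query.id}: alignment covers only {covered}/{BOVINE_LENGTH} bovine sites",
            stacklevel=2,
        )
    return aln


def detect_substitutions(query: OpsinSequence, reference: OpsinSequence,
                         bovine: Optional[str] = None) -> list[Substitution]:
    """Residue differences between query and reference in bovine numbering.

    Only sites where both sequences carry a residue are compared; gap
    columns are excluded.  Sorted by site.
    """
    q_map = assign_bovine_numbering(query, bovine).site_map()
    r_map = assign_bovine_numbering(reference, bovine).site_map()
    subs = [
        Substitution(site, r_map[site], q_map[site])
        for site in sorted(q_map.keys() & r_map.keys())
        if q_map[site] != r_map[site]
    ]
    return subs


def percent_identity(a: str, b: str) -> float:
    """Fraction of identical columns among columns where both have residues.

    'X' residues are treated as unknown: columns containing X count in
    neither numerator nor denominator.
    """
    aln = align_pair(a, b)
    both = [
        (q, r) for q, r, _ in aln.columns
        if q is not None and r is not None and q != "X" and r != "X"
    ]
    if not both:
        raise ValueError("no comparable columns")
    return sum(q == r for q, r in both) / len(both)


def in_transmembrane(site: int, tm_ranges: Optional[Sequence[tuple[int, int]]] = None) -> bool:
    """True iff a bovine-numbered site lies in a transmembrane helix."""
    if not 1 <= site <= BOVINE_LENGTH:
        raise ValueError(f"site {site} outside 1..{BOVINE_LENGTH}")
    if tm_ranges is None:
        tm_ranges = default_tm_ranges()
    return any(lo <= site <= hi for lo, hi in tm_ranges)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path) -> list[OpsinSequence]:
    """Read opsins from FASTA; description carries the class as 'class=RH2'.

    Records whose letters are all in {A,C,G,T,N} are taken as coding
    sequence and translated; anything else is read as amino acids.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cls = _parse_class(rec.description)
        s = str(rec.seq).upper()
        if set(s) <= set("ACGTN"):
            out.append(OpsinSequence(rec.id, cls, translate_cds(s), nucleotide_cds=s))
        else:
            out.append(OpsinSequence(rec.id, cls, s))
    return out


def write_fasta(seqs: Iterable[OpsinSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.amino_acids), id=s.id, description=f"class={s.opsin_class}")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_alignment_fasta(aln: NumberedAlignment, path) -> None:
    """Export a pairwise alignment as two gapped FASTA records."""
    q = "".join(c[0] or "-" for c in aln.columns)
    r = "".join(c[1] or "-" for c in aln.columns)
    records = [
        SeqRecord(Seq(q), id=aln.query_id, description=""),
        SeqRecord(Seq(r), id=aln.reference_id, description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_class(description: str) -> str:
    for token in description.split():
        if token.startswith("class="):
            return token.split("=", 1)[1]
    raise ValueError(f"FASTA description lacks 'class=' tag: {description!r}")
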