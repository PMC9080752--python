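"""Visual-pigment λmax prediction from tuning-site substitutions.

A pigment's peak absorbance (λmax) is predicted by starting from a
reference pigment whose λmax is known from in-vitro reconstitution and
adding the documented spectral shift of every substitution the query
carries at a known tuning site.  Shifts are treated as additive.

Two rules assign a shift to a substitution at a known tuning site:

``documented``
    the exact (site, from, to) exchange has a measured effect;
``polarity_matched``
    the exchange is undocumented but changes side-chain polarity in the
    same direction (polar→nonpolar or the reverse) as a documented
    exchange at the same site, whose shift is borrowed.

Substitutions at known tuning sites that do not change polarity receive
no shift.  Polarity-changing substitutions inside transmembrane helices
at or near known tuning sites that receive no shift are flagged as
candidates that may explain residual disagreement with measured λmax.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import yaml

from .opsin_sequences import (
    OPSIN_CLASSES,
    OpsinSequence,
    Substitution,
    default_tm_ranges,
    detect_substitutions,
    in_transmembrane,
)

# Two-class side-chain polarity scheme. C and W are borderline in the
# literature; both are treated as polar here (C has a thiol able to
# hydrogen-bond in the retinal pocket). Configurable via the
# `polar_residues` argument of classify_polarity / applicable_shifts.
POLAR_RESIDUES = frozenset("STCYNQDEKRHW")
NONPOLAR_RESIDUES = frozenset("AVLIPFMG")


def classify_polarity(residue: str, polar_residues: frozenset = POLAR_RESIDUES) -> str:
    """Classify a residue as 'polar' or 'nonpolar'."""
    if residue in polar_residues:
        return "polar"
    if residue in NONPOLAR_RESIDUES or (residue.isalpha() and residue != "X"
                                        and residue in "ACDEFGHIKLMNPQRSTVWY"):
        return "nonpolar"
    raise ValueError(f"cannot classify residue {residue!r}")


@dataclass(frozen=True)
class TuningSite:
    """A documented tuning-site substitution effect."""

    opsin_class: str
    bovine_site: int
    from_residue: str
    to_residue: str
    shift_nm: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.opsin_class not in OPSIN_CLASSES:
            raise ValueError(f"unknown opsin class {self.opsin_class!r}")
        if self.from_residue == self.to_residue:
            raise ValueError("from_residue must differ from to_residue")
        if not (self.shift_nm == self.shift_nm and abs(self.shift_nm) < 1e6):
            raise ValueError("shift_nm must be finite")


@dataclass
class ReferencePigment:
    """A reference opsin with an in-vitro measured λmax."""

    id: str
    opsin_class: str
    lambda_max_nm: float
    sequence: OpsinSequence

    def __post_init__(self) -> None:
        if not 340 <= self.lambda_max_nm <= 580:
            raise ValueError("reference λmax outside the visual-pigment range 340-580 nm")


@dataclass
class AppliedShift:
    substitution: Substitution
    shift_nm: float
    rule: str  # "documented" | "polarity_matched"


@dataclass
class Candidate:
    substitution: Substitution
    note: str


@dataclass
class PredictionResult:
    """Audit trail of a λmax prediction."""

    query_id: str
    reference_id: str
    reference_lambda_max_nm: float
    applied: list[AppliedShift]
    predicted_lambda_max_nm: float
    candidates: list[Candidate]

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "reference_id": self.reference_id,
            "reference_lambda_max_nm": self.reference_lambda_max_nm,
            "predicted_lambda_max_nm": self.predicted_lambda_max_nm,
            "applied": [
                {"substitution": str(a.substitution), "shift_nm": a.shift_nm, "rule": a.rule}
                for a in self.applied
            ],
            "candidates": [
                {"substitution": str(c.substitution), "note": c.note}
                for c in self.candidates
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def load_tuning_table(path=None) -> list[TuningSite]:
    """Load a tuning table from TSV or YAML; default is the shipped table."""
    if path is None:
        with resources.files("ovk.data").joinpath("tuning_sites.tsv").open() as fh:
            return _parse_tsv(fh)
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        return [TuningSite(r["opsin_class"], int(r["bovine_site"]), r["from_residue"],
                           r["to_residue"], float(r["shift_nm"]), r.get("source", ""))
                for r in rows]
    with open(path) as fh:
        return _parse_tsv(fh)


def _parse_tsv(fh) -> list[TuningSite]:
    reader = csv.DictReader(fh, delimiter="\t")
    return [TuningSite(r["opsin_class"], int(r["bovine_site"]), r["from_residue"],
                       r["to_residue"], float(r["shift_nm"]), r.get("source", ""))
            for r in reader]


def applicable_shifts(
    subs: Sequence[Substitution],
    opsin_class: str,
    tuning_table: Sequence[TuningSite],
    polar_residues: frozenset = POLAR_RESIDUES,
) -> tuple[list[AppliedShift], list[Candidate]]:
    """Assign shifts to substitutions at known tuning sites.

    Returns (applied, ambiguous): at most one shift per substitution;
    substitutions whose polarity match is ambiguous (several documented
    exchanges at the site agree in polarity direction but disagree in
    shift) receive no shift and are returned as candidates so the
    prediction stays auditable.
    """
    table = [t for t in tuning_table if t.opsin_class == opsin_class]
    applied: list[AppliedShift] = []
    ambiguous: list[Candidate] = []
    for sub in subs:
        rows = [t for t in table if t.bovine_site == sub.bovine_site]
        if not rows:
            continue
        exact = [t for t in rows
                 if t.from_residue == sub.from_residue and t.to_residue == sub.to_residue]
        if exact:
            shifts = sorted({t.shift_nm for t in exact})
            if len(shifts) > 1:
                ambiguous.append(Candidate(sub, "ambiguous: conflicting documented shifts"))
                continue
            applied.append(AppliedShift(sub, shifts[0], "documented"))
            continue
        transition = (classify_polarity(sub.from_residue, polar_residues),
                      classify_polarity(sub.to_residue, polar_residues))
        if transition[0] == transition[1]:
            # known site, but no polarity change: no effect assigned
            continue
        matched = [
            t for t in rows
            if (classify_polarity(t.from_residue, polar_residues),
                classify_polarity(t.to_residue, polar_residues)) == transition
        ]
        if not matched:
            continue
        shifts = sorted({t.shift_nm for t in matched})
        if len(shifts) > 1:
            ambiguous.append(Candidate(sub, "ambiguous: multiple polarity-matched shifts"))
            continue
        applied.append(AppliedShift(sub, shifts[0], "polarity_matched"))
    return applied, ambiguous


def flag_polarity_candidates(
    subs: Sequence[Substitution],
    tuning_table: Sequence[TuningSite],
    opsin_class: str,
    tm_predicate=in_transmembrane,
    proximity: int = 2,
    polar_residues: frozenset = POLAR_RESIDUES,
) -> list[Candidate]:
    """Flag polarity-changing TM substitutions near known tuning sites.

    A substitution is flagged when it changes polarity, lies inside a
    transmembrane helix, and sits at or within `proximity` residues of a
    known tuning site of the class.  These are plausible but unquantified
    tuning effects.
    """
    if proximity < 0:
        raise ValueError("proximity must be >= 0")
    known_sites = sorted({t.bovine_site for t in tuning_table if t.opsin_class == opsin_class})
    out = []
    for sub in subs:
        if classify_polarity(sub.from_residue, polar_residues) == \
           classify_polarity(sub.to_residue, polar_residues):
            continue
        if not tm_predicate(sub.bovine_site):
            continue
        near = [s for s in known_sites if abs(s - sub.bovine_site) <= proximity]
        if near:
            out.append(Candidate(
                sub, f"polarity change near known tuning site {near[0]}"))
    return out


def predict_lambda_max(
    query: OpsinSequence,
    reference: ReferencePigment,
    tuning_table: Optional[Sequence[TuningSite]] = None,
    bovine: Optional[str] = None,
    proximity: int = 2,
    polar_residues: frozenset = POLAR_RESIDUES,
) -> PredictionResult:
    """Predict a query opsin's λmax from a reference pigment.

    predicted λmax = reference λmax + Σ applicable shifts (additive).
    Candidates list polarity-changing transmembrane substitutions near
    known tuning sites that received no shift, plus ambiguous matches.
    """
    if query.opsin_class != reference.opsin_class:
        raise ValueError(
            f"opsin class mismatch: query {query.opsin_class}, "
            f"reference {reference.opsin_class}")
    if tuning_table is None:
        tuning_table = load_tuning_table()
    subs = detect_substitutions(query, reference.sequence, bovine)
    applied, ambiguous = applicable_shifts(subs, query.opsin_class, tuning_table,
                                           polar_residues)
    shifted = {a.substitution for a in applied}
    unshifted = [s for s in subs if s not in shifted]
    candidates = ambiguous + flag_polarity_candidates(
        unshifted, tuning_table, query.opsin_class,
        proximity=proximity, polar_residues=polar_residues)
    predicted = reference.lambda_max_nm + sum(a.shift_nm for a in applied)
    return PredictionResult(
        query_id=query.id,
        reference_id=reference.id,
        reference_lambda_max_nm=reference.lambda_max_nm,
        applied=applied,
        predicted_lambda_max_nm=predicted,
        candidates=candidates,
    )
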