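"""Mapping cross-links onto an oligomer assembly.

A lysine-lysine cross-link observed by mass spectrometry constrains the
Calpha-Calpha distance between the two residues to roughly the linker
span (we use 30 A for BS3).  In a symmetric oligomer the same residue
pair exists in several geometric contexts; for each pair we report the
minimum Calpha-Calpha distance in four contexts:

* ``intrasubunit``   -- within one chain,
* ``within_dimer``   -- between the two chains of a dimer,
* ``within_disc``    -- between non-dimer chains of the same disc,
* ``between_discs``  -- between chains of the two discs.

Cross-links are also assigned an evidence class 1-5 from gel-band and
isotope-hybrid observations:

1. intrasubunit,
2. intra- and intersubunit,
3. intra- or intersubunit,
4. inter- and possibly intrasubunit,
5. intra- and possibly intersubunit.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import AssemblyMap, Structure

__all__ = [
    "CONTEXTS", "DistanceQuartet", "CrossLinkRecord", "EvidenceError",
    "context_distances", "classify_evidence", "validate_constraints",
    "crosslink_report", "load_crosslink_table", "bundled_crosslink_table",
    "DEFAULT_THRESHOLD",
]

CONTEXTS = ("intrasubunit", "within_dimer", "within_disc", "between_discs")
DEFAULT_THRESHOLD = 30.0  # A, Calpha-Calpha constraint for BS3/DSS

_RELATION_OF_CONTEXT = {
    "intrasubunit": "same_subunit",
    "within_dimer": "same_dimer",
    "within_disc": "same_disc",
    "between_discs": "other_disc",
}

# which context distances can satisfy a cross-link of a given class
CLASS_CONTEXTS = {
    1: ("intrasubunit",),
    2: CONTEXTS,
    3: ("intrasubunit", "within_dimer"),
    4: CONTEXTS,
    5: ("intrasubunit",),  # intrasubunit primary; other contexts advisory
}


class EvidenceError(ValueError):
    """Raised for cross-link records without any detection evidence."""


@dataclass(frozen=True)
class DistanceQuartet:
    """Context-specific minimum Calpha-Calpha distances for a residue pair.

    A context is None when no chain pair in that relation has both
    Calpha atoms modelled.
    """

    pos_a: int
    pos_b: int
    distances: dict[str, float | None] = field(hash=False, default_factory=dict)

    def __post_init__(self) -> None:
        for ctx in CONTEXTS:
            self.distances.setdefault(ctx, None)
        for v in self.distances.values():
            if v is not None and v < 0:
                raise ValueError("distances must be >= 0")

    def __getitem__(self, ctx: str) -> float | None:
        return self.distances[ctx]

    @property
    def any_defined(self) -> bool:
        return any(v is not None for v in self.distances.values())


@dataclass
class CrossLinkRecord:
    """One cross-linked peptide pair with its detection evidence.

    ``bands`` is a subset of {IG_M, IG_D, IS} (in-gel monomer band,
    in-gel dimer band, in-solution digest); ``hybrid`` is Y / Y_star /
    N / ND, where Y_star marks hybrids from the wild-type x V181A
    mixing experiment.  ``published_class`` (optional) is the class
    assigned in the source dataset and acts as a per-record override.
    """

    pos_a: int
    pos_b: int
    peptide_a: str = ""
    peptide_b: str = ""
    quartet: DistanceQuartet | None = None
    bands: frozenset[str] = frozenset()
    hybrid: str = "ND"
    published_class: int | None = None


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def context_distances(assembly: Structure, amap: AssemblyMap,
                      pos_a: int, pos_b: int) -> DistanceQuartet:
    """Minimum Calpha-Calpha distance per context over all ordered chain
    pairs in that relation.

    Chains without a modelled Calpha at a position are skipped; a
    context with no valid chain pair yields None with a warning.
    """
    chains = amap.chains()
    ca_a = {c: assembly.ca(c, pos_a) for c in chains}
    ca_b = {c: assembly.ca(c, pos_b) for c in chains}
    if all(v is None for v in ca_a.values()) or \
            all(v is None for v in ca_b.values()):
        warnings.warn(f"Calpha absent in all chains for pair "
                      f"({pos_a}, {pos_b})", stacklevel=2)
        return DistanceQuartet(pos_a, pos_b, {c: None for c in CONTEXTS})

    best: dict[str, float | None] = {c: None for c in CONTEXTS}
    for c1 in chains:
        if ca_a[c1] is None:
            continue
        for c2 in chains:
            if ca_b[c2] is None:
                continue
            rel = amap.relation(c1, c2)
            ctx = {v: k for k, v in _RELATION_OF_CONTEXT.items()}[rel]
            d = float(np.linalg.norm(ca_a[c1] - ca_b[c2]))
            if best[ctx] is None or d < best[ctx]:
                best[ctx] = d
    missing = [c for c in CONTEXTS if best[c] is None]
    if missing:
        warnings.warn(f"no modelled chain pair for contexts {missing} of "
                      f"pair ({pos_a}, {pos_b})", stacklevel=2)
    return DistanceQuartet(pos_a, pos_b, best)


# ---------------------------------------------------------------------------
# evidence classification
# ---------------------------------------------------------------------------

def classify_evidence(bands: frozenset[str] | set[str] | str,
                      hybrid: str | None = None) -> int:
    """Assign the evidence class 1-5 from gel bands and hybrid status.

    Decision table: a hybrid cross-link (Y or Y_star) proves
    intersubunit linkage, so with a monomer-band observation it is
    class 2 (intra- and intersubunit) and without one class 4; a
    cross-link seen only in non-hybrid form (N) is class 1
    (intrasubunit); when the hybrid experiment is inconclusive (ND), a
    monomer-band observation gives class 5 and a dimer-band-only
    observation class 3.
    """
    if isinstance(bands, CrossLinkRecord):
        record = bands
        bands, hybrid = record.bands, record.hybrid
    bands = frozenset(bands) if not isinstance(bands, str) else frozenset([bands])
    hybrid = {"Y*": "Y_star"}.get(hybrid, hybrid)
    if not bands:
        raise EvidenceError("cross-link record has no detection evidence")
    if hybrid in ("Y", "Y_star"):
        return 2 if "IG_M" in bands else 4
    if hybrid == "N":
        return 1
    if hybrid == "ND":
        return 5 if "IG_M" in bands else 3
    raise EvidenceError(f"unknown hybrid status {hybrid!r}")


# ---------------------------------------------------------------------------
# constraint validation
# ---------------------------------------------------------------------------

def validate_constraints(records: list[CrossLinkRecord],
                         threshold: float = DEFAULT_THRESHOLD,
                         contexts: tuple[str, ...] | None = None) -> dict:
    """Check cross-links against the Calpha-Calpha distance constraint.

    A cross-link is satisfied when ANY class-compatible context distance
    is <= ``threshold`` (pass ``contexts`` to override the per-class
    choice, e.g. ``('intrasubunit',)``).  Records without any modelled
    distance (flexible-arm residues) are unevaluable, not violations.
    """
    violations, satisfied, unevaluable = [], [], []
    for rec in records:
        quartet = rec.quartet
        if quartet is None or not quartet.any_defined:
            unevaluable.append(rec)
            continue
        cls = rec.published_class or classify_evidence(rec.bands, rec.hybrid)
        allowed = contexts if contexts is not None else CLASS_CONTEXTS[cls]
        dists = {c: quartet[c] for c in allowed if quartet[c] is not None}
        if not dists:
            unevaluable.append(rec)
            continue
        if any(d <= threshold for d in dists.values()):
            satisfied.append(rec)
        else:
            violations.append({"record": rec, "distances": dists})
    return {"threshold": threshold,
            "n_evaluated": len(satisfied) + len(violations),
            "satisfied": satisfied,
            "violations": violations,
            "unevaluable": unevaluable}


# ---------------------------------------------------------------------------
# report / table I/O
# ---------------------------------------------------------------------------

def load_crosslink_table(path: str | Path) -> list[CrossLinkRecord]:
    """Read a cross-link evidence TSV.

    Expected columns: pos_a, pos_b, peptide_a, peptide_b, d_intra,
    d_dimer, d_disc, d_between, bands (comma-separated IG-M/IG-D/IS),
    hybrid (Y, Y*, N, ND), published_class.  '.' marks an absent
    distance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        def dist(col: str) -> float | None:
            v = row[col]
            return None if v in (".", "", None) or pd.isna(v) else float(v)

        dists = {"intrasubunit": dist("d_intra"),
                 "within_dimer": dist("d_dimer"),
                 "within_disc": dist("d_disc"),
                 "between_discs": dist("d_between")}
        quartet = DistanceQuartet(int(row.pos_a), int(row.pos_b), dists)
        bands = frozenset(b.strip().replace("-", "_")
                          for b in str(row.bands).split(",") if b.strip())
        pub = row.get("published_class")
        records.append(CrossLinkRecord(
            pos_a=int(row.pos_a), pos_b=int(row.pos_b),
            peptide_a=row.peptide_a, peptide_b=row.peptide_b,
            quartet=quartet if quartet.any_defined else quartet,
            bands=bands, hybrid=str(row.hybrid),
            published_class=None if pd.isna(pub) else int(pub)))
    return records


def bundled_crosslink_table() -> list[CrossLinkRecord]:
    """The published Hsp21 BS3 cross-link set (23 peptide-pair records)."""
    ref = importlib.resources.files("oligoxl.data") / "hsp21_crosslinks.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_crosslink_table(path)


def crosslink_report(records: list[CrossLinkRecord],
                     threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """One row per cross-linked peptide pair, ordered by (pos_a, pos_b).

    Columns carry the peptides, the four context distances, the
    evidence, the decision-table class, the published class when it
    overrides it (``deviation`` flags the disagreement rather than
    silently reclassifying), and the constraint status.
    """
    rows = []
    for rec in sorted(records, key=lambda r: (r.pos_a, r.pos_b,
                                              r.peptide_a, r.peptide_b)):
        rule_class = classify_evidence(rec.bands, rec.hybrid)
        cls = rec.published_class if rec.published_class is not None else rule_class
        status = validate_constraints([rec], threshold)
        if status["violations"]:
            constraint = "violated"
        elif status["satisfied"]:
            constraint = "satisfied"
        else:
            constraint = "unevaluable"
        q = rec.quartet
        rows.append({
            "pos_a": rec.pos_a, "pos_b": rec.pos_b,
            "peptide_a": rec.peptide_a, "peptide_b": rec.peptide_b,
            "d_intra": q["intrasubunit"] if q else None,
            "d_dimer": q["within_dimer"] if q else None,
            "d_disc": q["within_disc"] if q else None,
            "d_between": q["between_discs"] if q else None,
            "bands": ",".join(sorted(rec.bands)),
            "hybrid": rec.hybrid,
            "rule_class": rule_class,
            "class": cls,
            "deviation": rec.published_class is not None
                         and rec.published_class != rule_class,
            "constraint": constraint,
        })
    columns = ["pos_a", "pos_b", "peptide_a", "peptide_b", "d_intra",
               "d_dimer", "d_disc", "d_between", "bands", "hybrid",
               "rule_class", "class", "deviation", "constraint"]
    return pd.DataFrame(rows, columns=columns)


def report_to_tsv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, na_rep=".")


def report_from_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    df["deviation"] = df["deviation"].astype(bool)
    return df
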