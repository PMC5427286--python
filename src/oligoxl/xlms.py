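"""Cross-linking mass spectrometry arithmetic.

Covers the in-silico side of a BS3 cross-linking experiment on a
14N/15N-labelled protein mixture: tryptic digestion, monoisotopic
peptide and cross-link masses, prediction of the four-peak isotope
signature of a hybrid (14N-15N) cross-link, matching of candidates
against MS1 peak lists, MS/MS b/y fragment-coverage acceptance, and
isotope-dilution quantification.

BS3 (bis(sulfosuccinimidyl)suberate) reacts with primary amines (lysine
side chains and the protein N terminus).  An internal cross-link adds
the C8H10O2 spacer (+138.06808 Da); a hydrolysed dead-end adds C8H12O3
(+156.07864 Da).  Uniform 15N labelling shifts each peptide by
0.9970349 Da per nitrogen atom, so a cross-linked pair of peptides with
nA and nB nitrogens produces four mass states (AA, A*B, AB*, A*B*)
whose spacing identifies whether the two peptides came from the same or
from different subunits.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass
from scipy import stats

__all__ = [
    "Peptide", "CrossLinkSpecies", "IsotopeQuartet", "PeakList", "Spectrum",
    "SequenceError", "SpeciesError",
    "PROTON", "WATER", "DELTA_15N", "BS3_INTERNAL", "BS3_DEADEND",
    "MET_OXIDATION",
    "digest", "peptide_mass", "peptide_mz", "nitrogen_count",
    "crosslink_mass", "predict_quartet", "classify_hybrid",
    "match_candidates", "fragment_ions", "fragment_acceptance",
    "isotope_dilution_ratio",
]

PROTON = 1.00727646688
WATER = 18.0105646863
DELTA_15N = 0.9970349          # 15N - 14N monoisotopic mass difference, Da
BS3_INTERNAL = 138.06808       # C8H10O2 spacer, both ends reacted
BS3_DEADEND = 156.07864        # C8H12O3, one end hydrolysed
MET_OXIDATION = 15.994915

_AA_MASS = dict(_pmass.std_aa_mass)          # monoisotopic residue masses
_AA_NITROGEN = {aa: _pmass.std_aa_comp[aa]["N"]
                for aa in "ACDEFGHIKLMNPQRSTVWY"}

_VALID = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


class SequenceError(ValueError):
    """Illegal amino-acid sequence."""


class SpeciesError(ValueError):
    """Invalid cross-link species for the requested operation."""


def _check_sequence(seq: str) -> str:
    if not seq or not _VALID.match(seq):
        raise SequenceError(f"invalid amino-acid sequence: {seq!r}")
    return seq


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with its position in the mature protein.

    ``span`` is (start, end), 1-based inclusive; ``modifications`` maps
    residue position (protein numbering) to a mass delta in Da (e.g.
    Met oxidation +15.994915); ``label`` is '14N' or '15N'.
    """

    sequence: str
    span: tuple[int, int] = (0, 0)
    modifications: dict[int, float] = field(default_factory=dict, hash=False)
    label: str = "14N"
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.span != (0, 0) and (
                self.span[1] - self.span[0] + 1 != len(self.sequence)):
            raise SequenceError(
                f"span {self.span} does not match sequence length "
                f"{len(self.sequence)}")
        for pos in self.modifications:
            if self.span != (0, 0) and not (
                    self.span[0] <= pos <= self.span[1]):
                raise SequenceError(
                    f"modification at {pos} outside span {self.span}")

    def __hash__(self) -> int:
        return hash((self.sequence, self.span, self.label,
                     tuple(sorted(self.modifications.items()))))


@dataclass(frozen=True)
class CrossLinkSpecies:
    """A BS3 cross-linked peptide pair (or a dead-end single peptide).

    Linked sites must be lysines or the protein N terminus (residue 1).
    """

    peptide_a: Peptide
    peptide_b: Peptide | None
    site_a: int
    site_b: int | None = None
    linker: str = "BS3_internal"

    def __post_init__(self) -> None:
        if self.linker == "BS3_internal" and self.peptide_b is None:
            raise SpeciesError("internal cross-link needs two peptides")
        for pep, site in ((self.peptide_a, self.site_a),
                          (self.peptide_b, self.site_b)):
            if pep is None:
                continue
            if pep.span != (0, 0) and site is not None:
                res = pep.sequence[site - pep.span[0]]
                if res != "K" and site != 1:
                    raise SpeciesError(
                        f"linked site {site} ({res}) is neither lysine nor "
                        f"the protein N terminus")


@dataclass(frozen=True)
class IsotopeQuartet:
    """The four neutral masses of the label states AA, A*B, AB*, A*B*.

    ``*`` marks the uniformly 15N-labelled peptide; the spacing obeys
    m(A*B) - m(AA) = nA * 0.9970349 and
    m(A*B*) - m(AA) = (nA + nB) * 0.9970349.
    """

    masses: tuple[float, float, float, float]   # AA, A*B, AB*, A*B*
    n_a: int
    n_b: int

    def mz(self, charge: int = 1) -> tuple[float, float, float, float]:
        return tuple((m + charge * PROTON) / charge for m in self.masses)


@dataclass
class PeakList:
    """An MS1 peak list: m/z (sorted ascending) and intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("m/z must be > 0 and intensities >= 0")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def match(self, target_mz: float, ppm: float) -> int | None:
        """Index of the most intense peak within ``ppm`` of ``target_mz``,
        or None."""
        tol = target_mz * ppm * 1e-6
        lo = bisect_left(self.mz.tolist(), target_mz - tol)
        hi = bisect_right(self.mz.tolist(), target_mz + tol)
        if lo == hi:
            return None
        return lo + int(np.argmax(self.intensity[lo:hi]))


@dataclass
class Spectrum:
    """An MS/MS spectrum with its precursor."""

    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_intensity: float = 0.0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def digest(sequence: str, max_missed: int = 2) -> list[Peptide]:
    """Tryptic digest: cleave after K/R except before P.

    Returns every peptide with 0..``max_missed`` missed cleavages, with
    1-based inclusive spans into ``sequence``.
    """
    _check_sequence(sequence)
    cut_after = [i + 1 for i in range(len(sequence) - 1)
                 if sequence[i] in "KR" and sequence[i + 1] != "P"]
    bounds = [0] + cut_after + [len(sequence)]
    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            peptides.append(Peptide(sequence[start:end], (start + 1, end),
                                    missed_cleavages=missed))
    return peptides


# ---------------------------------------------------------------------------
# mass arithmetic
# ---------------------------------------------------------------------------

def nitrogen_count(peptide: Peptide | str) -> int:
    """Total nitrogen atoms (backbone amide plus side chains)."""
    seq = peptide if isinstance(peptide, str) else peptide.sequence
    _check_sequence(seq)
    return int(sum(_AA_NITROGEN[aa] for aa in seq))


def peptide_mass(peptide: Peptide | str) -> float:
    """Neutral monoisotopic mass, including modifications and 15N label."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    seq = peptide.sequence
    m = sum(_AA_MASS[aa] for aa in seq) + WATER
    m += sum(peptide.modifications.values())
    if peptide.label == "15N":
        m += nitrogen_count(peptide) * DELTA_15N
    elif peptide.label != "14N":
        raise SequenceError(f"unknown label {peptide.label!r}")
    return m


def peptide_mz(peptide: Peptide | str, charge: int = 1) -> float:
    """Monoisotopic m/z at the given positive charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(peptide) + charge * PROTON) / charge


def crosslink_mass(species: CrossLinkSpecies) -> float:
    """Neutral monoisotopic mass of an internal or dead-end species."""
    if species.linker == "BS3_internal":
        if species.peptide_b is None:
            raise SpeciesError("internal cross-link needs two peptides")
        return (peptide_mass(species.peptide_a)
                + peptide_mass(species.peptide_b) + BS3_INTERNAL)
    if species.linker == "BS3_deadend":
        return peptide_mass(species.peptide_a) + BS3_DEADEND
    raise SpeciesError(f"unknown linker {species.linker!r}")


# ---------------------------------------------------------------------------
# isotope quartets and hybrid classification
# ---------------------------------------------------------------------------

def predict_quartet(species: CrossLinkSpecies) -> IsotopeQuartet:
    """Predict the four label-state masses of an internal cross-link.

    The unlabeled mass AA is shifted by nA*Delta for A*B, nB*Delta for
    AB*, and (nA+nB)*Delta for A*B* (Delta = 0.9970349 Da).
    """
    if species.linker != "BS3_internal" or species.peptide_b is None:
        raise SpeciesError("isotope quartets are defined for internal "
                           "cross-links only")
    pa = Peptide(species.peptide_a.sequence, species.peptide_a.span,
                 dict(species.peptide_a.modifications), "14N")
    pb = Peptide(species.peptide_b.sequence, species.peptide_b.span,
                 dict(species.peptide_b.modifications), "14N")
    base = peptide_mass(pa) + peptide_mass(pb) + BS3_INTERNAL
    n_a, n_b = nitrogen_count(pa), nitrogen_count(pb)
    raw = (base, base + n_a * DELTA_15N, base + n_b * DELTA_15N,
           base + (n_a + n_b) * DELTA_15N)
    ordered = (raw[0], min(raw[1], raw[2]), max(raw[1], raw[2]), raw[3])
    return IsotopeQuartet(ordered, n_a, n_b)


def classify_hybrid(peaklist: PeakList, quartet: IsotopeQuartet,
                    ppm: float = 10.0, min_intensity: float = 0.0,
                    charge: int = 1) -> str:
    """Classify the isotope signature of a cross-link in an MS1 peak list.

    Returns ``'hybrid_signature'`` when both outer (AA, A*B*) and both
    mixed (A*B, AB*) peaks are present -- evidence that the two peptides
    can come from different subunits; ``'intra_signature'`` when only
    the outer pair is present; ``'not_detected'`` otherwise.  A single
    mixed peak is conservatively treated as not detected.
    """
    if len(peaklist.mz) == 0:
        return "not_detected"
    mzs = quartet.mz(charge)

    def present(target: float) -> bool:
        idx = peaklist.match(target, ppm)
        return idx is not None and peaklist.intensity[idx] >= min_intensity

    outer = present(mzs[0]) and present(mzs[3])
    mixed_a, mixed_b = present(mzs[1]), present(mzs[2])
    if outer and mixed_a and mixed_b:
        return "hybrid_signature"
    if outer and not mixed_a and not mixed_b:
        return "intra_signature"
    return "not_detected"


# ---------------------------------------------------------------------------
# candidate matching
# ---------------------------------------------------------------------------

def _link_sites(pep: Peptide) -> list[int]:
    """Positions (protein numbering) in a peptide that BS3 can react with:
    lysines that are not the cleaved C terminus, plus the protein
    N terminus."""
    start, _ = pep.span
    sites = [start + i for i, aa in enumerate(pep.sequence) if aa == "K"]
    if start == 1 and 1 not in sites:
        sites.insert(0, 1)
    return sites


def match_candidates(peaklist: PeakList, sequences: list[str] | str,
                     ppm: float = 10.0, max_missed: int = 2,
                     charge: int = 1) -> list[dict]:
    """Enumerate digest peptide pairs and dead-ends of the supplied
    sequences and return those whose m/z matches an MS1 peak within
    ``ppm``.  Each candidate dict carries the species, its theoretical
    m/z, the matched peak m/z and the signed ppm error.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    peptides: list[Peptide] = []
    for seq in sequences:
        peptides.extend(digest(seq, max_missed))
    linkable = [(p, _link_sites(p)) for p in peptides]
    linkable = [(p, s) for p, s in linkable if s]

    candidates: list[dict] = []
    seen: set[tuple] = set()

    def consider(species: CrossLinkSpecies) -> None:
        theo = (crosslink_mass(species) + charge * PROTON) / charge
        idx = peaklist.match(theo, ppm)
        if idx is None:
            return
        key = (species.peptide_a.sequence, species.site_a,
               species.peptide_b.sequence if species.peptide_b else None,
               species.site_b, species.linker)
        if key in seen:
            return
        seen.add(key)
        obs = float(peaklist.mz[idx])
        candidates.append({
            "species": species,
            "theoretical_mz": theo,
            "observed_mz": obs,
            "ppm_error": (obs - theo) / theo * 1e6,
            "intensity": float(peaklist.intensity[idx]),
        })

    for i, (pa, sites_a) in enumerate(linkable):
        for site_a in sites_a:
            consider(CrossLinkSpecies(pa, None, site_a, None, "BS3_deadend"))
            for pb, sites_b in linkable[i:]:
                for site_b in sites_b:
                    consider(CrossLinkSpecies(pa, pb, site_a, site_b,
                                              "BS3_internal"))
    candidates.sort(key=lambda c: c["theoretical_mz"])
    return candidates


# ---------------------------------------------------------------------------
# MS/MS fragment acceptance
# ---------------------------------------------------------------------------

def fragment_ions(species: CrossLinkSpecies, which: str = "a") -> np.ndarray:
    """Singly-charged b/y fragment m/z values for one peptide of a
    cross-linked species.

    Fragments containing the linked residue carry the spacer plus the
    full mass of the partner peptide.
    """
    pep = species.peptide_a if which == "a" else species.peptide_b
    if pep is None:
        raise SpeciesError("species has no peptide B")
    site = species.site_a if which == "a" else species.site_b
    partner = species.peptide_b if which == "a" else species.peptide_a
    if species.linker == "BS3_internal":
        extra = BS3_INTERNAL + peptide_mass(partner)
    else:
        extra = BS3_DEADEND
    start, _ = pep.span
    link_idx = (site - start) if (pep.span != (0, 0) and site is not None) else None
    seq = pep.sequence
    res = [_AA_MASS[aa] for aa in seq]
    for pos, delta in pep.modifications.items():
        res[pos - start] += delta
    if pep.label == "15N":
        for i, aa in enumerate(seq):
            res[i] += _AA_NITROGEN[aa] * DELTA_15N

    ions = []
    prefix = np.cumsum(res)
    total = prefix[-1]
    for i in range(1, len(seq)):          # b_i and y_(n-i)
        b = prefix[i - 1] + PROTON
        y = total - prefix[i - 1] + WATER + PROTON
        if link_idx is not None:
            if link_idx <= i - 1:
                b += extra
            else:
                y += extra
        ions.extend([b, y])
    return np.array(sorted(ions))


def fragment_acceptance(species: CrossLinkSpecies, spectrum: Spectrum,
                        frag_tol: float = 0.05, ms1_ppm: float = 10.0,
                        min_score: float = 25.0,
                        min_precursor_intensity: float = 1000.0,
                        min_coverage: float = 0.30) -> dict:
    """Score an MS/MS spectrum against a cross-linked species.

    The theoretical b/y ladders of both peptides (linker plus partner
    mass on the linked residue's fragments) are matched within
    ``frag_tol`` Da.  The species is accepted when the matched fraction
    reaches ``min_coverage`` on both peptides, the match score exceeds
    ``min_score`` and the precursor peak intensity exceeds
    ``min_precursor_intensity``.  The score is -10*log10 of the binomial
    tail probability of the observed total match count under random
    peak placement (the >25 threshold semantics of a search-engine
    score, with an explicit null model).
    """
    theo_mz = (crosslink_mass(species) + spectrum.charge * PROTON) / spectrum.charge
    if abs(spectrum.precursor_mz - theo_mz) / theo_mz * 1e6 > ms1_ppm:
        raise SpeciesError(
            f"precursor {spectrum.precursor_mz:.4f} does not match species "
            f"m/z {theo_mz:.4f} within {ms1_ppm} ppm")

    def coverage(which: str) -> tuple[float, int, int]:
        ions = fragment_ions(species, which)
        matched = 0
        for ion in ions:
            lo = np.searchsorted(spectrum.mz, ion - frag_tol)
            hi = np.searchsorted(spectrum.mz, ion + frag_tol)
            if hi > lo:
                matched += 1
        return matched / len(ions), matched, len(ions)

    cov_a, k_a, n_a = coverage("a")
    if species.peptide_b is not None:
        cov_b, k_b, n_b = coverage("b")
    else:
        cov_b, k_b, n_b = cov_a, 0, 0

    # null model: probability that a random theoretical ion lands within
    # +/- frag_tol of any observed peak
    if len(spectrum.mz) > 1:
        span = float(spectrum.mz[-1] - spectrum.mz[0]) + 2 * frag_tol
    else:
        span = 1000.0
    p_rand = min(1.0, len(spectrum.mz) * 2 * frag_tol / span)
    k, n = k_a + k_b, n_a + n_b
    tail = float(stats.binom.sf(k - 1, n, p_rand)) if n else 1.0
    score = -10.0 * math.log10(max(tail, 1e-300))

    accepted = (cov_a >= min_coverage and cov_b >= min_coverage
                and score > min_score
                and spectrum.precursor_intensity > min_precursor_intensity)
    return {"coverage_a": cov_a, "coverage_b": cov_b, "score": score,
            "accepted": bool(accepted)}


# ---------------------------------------------------------------------------
# isotope-dilution quantification
# ---------------------------------------------------------------------------

def isotope_dilution_ratio(peaklist: PeakList, light_mz: float,
                           heavy_mz: float, ppm: float = 10.0) -> dict:
    """Light/heavy intensity ratio against a 15N-labelled reference.

    A missing light peak gives ratio 0 (fully digested analyte); a
    missing heavy reference flags the ratio as undefined.
    """
    li = peaklist.match(light_mz, ppm)
    hi = peaklist.match(heavy_mz, ppm)
    if hi is None:
        return {"ratio": math.nan, "defined": False}
    heavy = float(peaklist.intensity[hi])
    light = float(peaklist.intensity[li]) if li is not None else 0.0
    return {"ratio": light / heavy if heavy > 0 else math.nan,
            "defined": heavy > 0}
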