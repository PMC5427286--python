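"""Synthetic ground-truth generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and
returns the generated object together with a :class:`SyntheticTruth`
sidecar recording the parameters, so any result downstream can be
checked against known ground truth without external data.

The generators emulate the study conditions of a dodecameric small
heat-shock protein: double-disc assemblies with a screw twist near 30
degrees and separation near 35 A; MS1 peak lists with 14N/15N isotope
quartets, <=10 ppm mass jitter and uniform decoys; scattering curves of
dodecamer/hexamer mixtures with Gaussian noise; and rendered density
maps with half-map noise and inserted Gaussian blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import density as _density
from . import saxs as _saxs
from . import xlms as _xlms
from .structures import AssemblyMap, Atom, ScrewTransform, Structure, build_assembly

__all__ = [
    "SyntheticTruth", "make_toy_dimer", "make_assembly_fixture",
    "make_peaklists", "make_saxs_mixture", "make_map_fixture",
    "hsp21_synthetic_sequence",
]


@dataclass
class SyntheticTruth:
    """Generator parameters serialized alongside every dataset."""

    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_file(self, path: str | Path) -> None:
        lines = [f"generator={self.generator}", f"seed={self.seed}"]
        for k in sorted(self.params):
            lines.append(f"{k}={_serialize(self.params[k])}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticTruth":
        data: dict = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            k, v = line.split("=", 1)
            data[k] = v
        gen = data.pop("generator")
        seed = data.pop("seed")
        seed = None if seed == "None" else int(seed)
        return cls(gen, seed, {k: _deserialize(v) for k, v in data.items()})


def _serialize(v) -> str:
    if isinstance(v, (list, tuple, np.ndarray)):
        return ",".join(_serialize(x) for x in np.asarray(v).ravel())
    return repr(v) if isinstance(v, str) else str(v)


def _deserialize(s: str):
    if "," in s:
        return [_deserialize(x) for x in s.split(",")]
    if s.startswith("'") and s.endswith("'"):
        return s[1:-1]
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    if s in ("True", "False"):
        return s == "True"
    return s


def hsp21_synthetic_sequence() -> str:
    """The bundled synthetic stand-in for mature Hsp21 (184 aa).

    Every published tryptic peptide sits at its published span; the
    unsequenced stretches are K/R-free filler, so digestion and mass
    arithmetic on the published peptides are exact while the filler
    never contributes spurious cleavage sites.
    """
    import importlib.resources
    ref = importlib.resources.files("oligoxl.data") / "hsp21_synthetic.fasta"
    lines = ref.read_text().splitlines()
    return "".join(l.strip() for l in lines if not l.startswith(">"))


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def make_toy_dimer(n_residues: int = 30, seed: int = 0,
                   offset: float = 22.0) -> Structure:
    """A compact two-chain Calpha trace with a shared interface.

    Chain A is a deterministic self-avoiding-ish compact walk; chain B
    is chain A rotated 180 degrees about an in-plane 2-fold axis
    through the dimer centre, so the two chains superpose exactly after
    the dimer's own 2-fold.  The dimer centre sits ``offset`` A from
    the origin (the 3-fold axis), ready for disc replication.
    """
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    while len(pts) < n_residues:
        step = rng.normal(size=3)
        step *= 3.8 / np.linalg.norm(step)
        cand = pts[-1] + step
        # keep compact and self-avoiding
        if np.linalg.norm(cand) > 3.8 * max(2.5, n_residues ** 0.55):
            continue
        if len(pts) > 1 and min(np.linalg.norm(np.asarray(pts[:-1]) - cand,
                                               axis=1)) < 3.5:
            continue
        pts.append(cand)
    a_xyz = np.asarray(pts)
    a_xyz = a_xyz - a_xyz.mean(axis=0) + np.array([4.0, 0.0, 0.0])
    # dimer 2-fold: 180 deg about the z axis through the dimer centre
    flip = np.diag([-1.0, -1.0, 1.0])
    b_xyz = a_xyz @ flip.T

    st = Structure()
    for chain, xyz in (("A", a_xyz), ("B", b_xyz)):
        for i, p in enumerate(xyz):
            st.atoms.append(Atom("C", "CA", i + 1, chain, p.copy()))
        st.chain_sequences[chain] = "A" * len(xyz)
    # place the dimer centre off-axis so disc replication does not clash
    return st.transformed(np.eye(3), np.array([offset, 0.0, 0.0]))


def make_assembly_fixture(theta: float = 30.0, d: float = 35.0,
                          seed: int = 0, n_residues: int = 30,
                          ) -> tuple[Structure, AssemblyMap, SyntheticTruth]:
    """A dodecamer with known screw parameters."""
    dimer = make_toy_dimer(n_residues=n_residues, seed=seed)
    screw = ScrewTransform(theta_deg=theta, d=d)
    assembly, amap = build_assembly(dimer, screw)
    truth = SyntheticTruth("make_assembly_fixture", seed,
                           {"theta": theta, "d": d,
                            "n_residues": n_residues})
    return assembly, amap, truth


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

def make_peaklists(sequences: list[str] | str,
                   true_crosslinks: list[tuple[str, str]],
                   ppm_jitter: float = 0.0, decoy_density: float = 0.0,
                   seed: int = 0, hybrid: bool = True,
                   intensity: float = 1e5,
                   mz_range: tuple[float, float] = (300.0, 5000.0),
                   ) -> tuple[_xlms.PeakList, SyntheticTruth]:
    """MS1 peak list containing the isotope quartets of true cross-links.

    ``true_crosslinks`` are (peptide_a, peptide_b) sequence pairs; each
    contributes its quartet (all four peaks when ``hybrid``, only the
    outer 14N/14N and 15N/15N pair otherwise) with uniform m/z jitter
    bounded by ``ppm_jitter``.  Decoys are uniform random peaks at
    ``decoy_density`` peaks per Da over ``mz_range``.
    """
    rng = np.random.default_rng(seed)
    mzs: list[float] = []
    intensities: list[float] = []
    truth_mz: list[float] = []
    for seq_a, seq_b in true_crosslinks:
        pa, pb = _xlms.Peptide(seq_a), _xlms.Peptide(seq_b)
        species = _xlms.CrossLinkSpecies(pa, pb, None, None, "BS3_internal")
        quartet = _xlms.predict_quartet(species)
        four = quartet.mz(1)
        chosen = four if hybrid else (four[0], four[3])
        for mz in chosen:
            jit = rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6 * mz
            mzs.append(mz + jit)
            intensities.append(intensity * rng.uniform(0.5, 1.0))
            truth_mz.append(mz)
    n_decoys = int(decoy_density * (mz_range[1] - mz_range[0]))
    for _ in range(n_decoys):
        mzs.append(rng.uniform(*mz_range))
        intensities.append(intensity * rng.uniform(0.01, 1.0))
    if not mzs:
        mzs, intensities = [mz_range[0]], [0.0]
    peaklist = _xlms.PeakList(np.asarray(mzs), np.asarray(intensities))
    truth = SyntheticTruth("make_peaklists", seed, {
        "n_true": len(true_crosslinks), "ppm_jitter": ppm_jitter,
        "decoy_density": decoy_density, "hybrid": hybrid,
        "true_mz": truth_mz})
    return peaklist, truth


def make_msms_spectrum(species: _xlms.CrossLinkSpecies,
                       keep_fraction_a: float = 1.0,
                       keep_fraction_b: float = 1.0,
                       charge: int = 3, seed: int = 0,
                       precursor_intensity: float = 1e4) -> _xlms.Spectrum:
    """A synthetic MS/MS spectrum from the theoretical b/y ladders,
    optionally ablating a fraction of each peptide's ions."""
    rng = np.random.default_rng(seed)
    mz_parts = []
    for which, keep in (("a", keep_fraction_a), ("b", keep_fraction_b)):
        if which == "b" and species.peptide_b is None:
            continue
        ions = _xlms.fragment_ions(species, which)
        n_keep = int(round(keep * len(ions)))
        if n_keep:
            mz_parts.append(rng.choice(ions, size=n_keep, replace=False))
    mz = (np.concatenate(mz_parts) if mz_parts
          else np.array([100.0]))
    prec = (_xlms.crosslink_mass(species) + charge * _xlms.PROTON) / charge
    return _xlms.Spectrum(prec, charge, mz, np.full(len(mz), 1e3),
                          precursor_intensity=precursor_intensity)


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

def make_oligomer_pools(q: np.ndarray, states: tuple[str, ...] = ("dodecamer", "hexamer"),
                        n_per_state: int = 50, arm_length: int = 20,
                        n_residues: int = 30, seed: int = 0,
                        mode: str = "outside") -> list[_saxs.ConformerPool]:
    """Conformer pools of toy oligomers with flexible arms.

    The rigid cores are built from the toy dimer: a double disc for the
    dodecamer, a single disc for the hexamer, one dimer for the dimer
    state.  One arm is grown per dimer (the flexible terminal arms),
    with per-conformer scattering curves precomputed on ``q``.
    """
    rng = np.random.default_rng(seed)
    dimer = make_toy_dimer(n_residues=n_residues, seed=seed)
    dodeca, _ = build_assembly(dimer, ScrewTransform(theta_deg=30.0, d=35.0))
    pools = []
    for state in states:
        if state == "dodecamer":
            core = dodeca.ca_coords()
            n_arms = 6
        elif state == "hexamer":
            # single trimer-of-dimers disc: C3 replication of the dimer
            ca = dimer.ca_coords()
            rots = [np.array([[np.cos(t), -np.sin(t), 0],
                              [np.sin(t), np.cos(t), 0],
                              [0, 0, 1.0]])
                    for t in np.radians([0.0, 120.0, 240.0])]
            core = np.vstack([ca @ R.T for R in rots])
            n_arms = 3
        elif state == "dimer":
            core = dimer.ca_coords()
            n_arms = 1
        else:
            raise ValueError(f"unknown state {state!r}")
        centre = core.mean(axis=0)
        radii = np.linalg.norm(core - centre, axis=1)
        anchors = core[np.argsort(radii)[-n_arms:]]
        pool = _saxs.generate_arms(core, anchors, arm_length=arm_length,
                                   n=n_per_state,
                                   seed=int(rng.integers(2 ** 31)),
                                   mode=mode, state=state, q=q)
        pools.append(pool)
    return pools


def make_saxs_mixture(fractions: dict[str, float], noise: float = 0.01,
                      q: np.ndarray | None = None, seed: int = 0,
                      pools: list[_saxs.ConformerPool] | None = None,
                      **pool_kwargs) -> tuple[_saxs.SAXSCurve, SyntheticTruth,
                                              list[_saxs.ConformerPool]]:
    """A noisy scattering curve of a known oligomer-state mixture.

    The curve is the fraction-weighted sum of the state-average Debye
    curves of freshly generated (or supplied) conformer pools, plus
    Gaussian noise with sigma(q) = noise * I(q).
    """
    if q is None:
        q = np.linspace(0.05, 3.0, 60)
    rng = np.random.default_rng(seed)
    if pools is None:
        pools = make_oligomer_pools(q, states=tuple(fractions), seed=seed,
                                    **pool_kwargs)
    I = np.zeros_like(q)
    for pool in pools:
        frac = fractions.get(pool.state, 0.0)
        if frac == 0 or len(pool) == 0:
            continue
        avg = np.mean([c.curve.intensity for c in pool.conformers], axis=0)
        I = I + frac * avg
    sigma = np.maximum(noise * I, I.max() * 1e-6)
    noisy = I + rng.normal(size=len(q)) * (noise * I)
    curve = _saxs.SAXSCurve(q, noisy, sigma)
    truth = SyntheticTruth("make_saxs_mixture", seed, {
        "fractions": [f"{k}:{v}" for k, v in sorted(fractions.items())],
        "noise": noise})
    return curve, truth, pools


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def make_map_fixture(structure: Structure | np.ndarray,
                     resolution: float = 10.0, voxel: float = 3.0,
                     noise_sd: float = 0.0, n_blobs: int = 0,
                     blob_amplitude: float = 5.0, seed: int = 0,
                     ) -> tuple[_density.DensityGrid, _density.DensityGrid,
                                _density.DensityGrid, SyntheticTruth]:
    """A rendered map plus two independent half-map noise realizations.

    Optional Gaussian blobs (recorded centres) are added to the base
    map before the half-maps are made, emulating unmodelled density.
    Returns (full map, half map 1, half map 2, truth).
    """
    rng = np.random.default_rng(seed)
    base = _density.render_map(structure, resolution, voxel)
    centres = []
    if n_blobs:
        lo = base.origin + 0.15 * voxel * np.array(base.values.shape)
        hi = base.origin + 0.85 * voxel * np.array(base.values.shape)
        sigma_b = resolution * _density.FWHM_TO_SIGMA
        axes = [np.arange(n) * voxel + base.origin[i]
                for i, n in enumerate(base.values.shape)]
        peak = base.values.max()
        # 4.5 sigma keeps blobs separable at half-peak contour levels
        min_sep = 4.5 * sigma_b
        attempts = 0
        while len(centres) < n_blobs:
            attempts += 1
            if attempts > 5000:
                raise ValueError(
                    f"cannot place {n_blobs} blobs {min_sep:.1f} A apart "
                    f"in this grid")
            c = rng.uniform(lo, hi)
            if centres and min(np.linalg.norm(np.asarray(centres) - c, axis=1)) < min_sep:
                continue
            centres.append(c)
            g = [np.exp(-0.5 * ((ax - c[i]) / sigma_b) ** 2)
                 for i, ax in enumerate(axes)]
            base.values += blob_amplitude * peak * np.einsum(
                "i,j,k->ijk", g[0], g[1], g[2])
    half1, half2 = base.copy(), base.copy()
    if noise_sd > 0:
        scale = noise_sd * base.values.std()
        half1.values = base.values + rng.normal(size=base.values.shape) * scale
        half2.values = base.values + rng.normal(size=base.values.shape) * scale
    truth = SyntheticTruth("make_map_fixture", seed, {
        "resolution": resolution, "voxel": voxel, "noise_sd": noise_sd,
        "n_blobs": n_blobs,
        "blob_centres": [list(c) for c in centres] if centres else 0})
    return base, half1, half2, truth
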