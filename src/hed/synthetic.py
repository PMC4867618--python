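"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its arguments plus an integer seed,
so fixtures are reproducible bit-for-bit and tests can assert recovery of
the generating parameters.

The peptide builder places backbone atoms (N, Cα, C, O, plus Cβ) from
ideal bond lengths and angles by sequential internal-coordinate
construction, with per-residue dihedrals taken from the secondary-structure
string: (φ, ψ) = (−57°, −47°) for H, (−135°, +135°) for E, and seeded
random draws from the broad extended basin (φ ∈ [−180°, −60°],
ψ ∈ [60°, 180°]) for C, with a minimum-distance rejection against chain
self-intersection.  Ensembles emulate a rigid core with mobile tails by
adding isotropic Gaussian coordinate noise whose σ switches between
``noise_core`` inside the core residue range and ``noise_tail`` outside.

Shift tables are random-coil values plus class offsets (helix moves Cα
down-field, Cβ slightly up-field; strand the opposite) plus Gaussian
noise; saturation-transfer intensity tables come from the same forward
model the fitter uses (:func:`hed.exchange.hetex_intensity`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csi import load_random_coil_table
from .errors import ValidationError
from .exchange import DEFAULT_DELAYS, hetex_intensity
from .io import AtomSite, IntensityTable, Model, StructureEnsemble

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: ideal backbone geometry: bond lengths (Å) and angles (deg)
BOND_N_CA, BOND_CA_C, BOND_C_N = 1.458, 1.525, 1.329
BOND_C_O, BOND_CA_CB = 1.231, 1.521
ANGLE_N_CA_C, ANGLE_CA_C_N, ANGLE_C_N_CA = 111.2, 116.2, 121.7
ANGLE_CA_C_O, ANGLE_C_CA_CB = 120.8, 110.1
DIHEDRAL_N_C_CA_CB = 122.55  # L-amino-acid improper
OMEGA = 180.0

#: per-class ideal dihedrals (φ, ψ), deg
CLASS_DIHEDRALS = {"H": (-57.0, -47.0), "E": (-135.0, 135.0)}
COIL_PHI_RANGE = (-180.0, -60.0)
COIL_PSI_RANGE = (60.0, 180.0)
MIN_CLASH_DIST = 2.5  # Å, Cα-Cα self-avoidance for coil sampling

#: secondary-shift offsets (ΔCα, ΔCβ) per class, ppm
DEFAULT_SHIFT_OFFSETS = {"H": (2.8, -0.5), "E": (-1.5, 2.2), "C": (0.0, 0.0)}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic chain/ensemble."""

    sequence: str
    ss_string: str
    chain_id: str = "A"
    first_residue: int = 1
    core_range: tuple[int, int] | None = None
    noise_core: float = 0.2
    noise_tail: float = 3.0
    n_models: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.ss_string):
            raise ValidationError("sequence and ss_string lengths differ")
        bad = set(self.ss_string) - {"H", "E", "C"}
        if bad:
            raise ValidationError(f"unknown secondary-structure classes {bad}")
        unknown = set(self.sequence.upper()) - set(ONE_TO_THREE)
        if unknown:
            raise ValidationError(f"unknown residue letters {unknown}")
        if self.noise_core < 0 or self.noise_tail < 0:
            raise ValidationError("noise must be >= 0")
        if self.n_models < 1:
            raise ValidationError("n_models must be >= 1")

    def residue_numbers(self) -> list[int]:
        return list(range(self.first_residue,
                          self.first_residue + len(self.sequence)))


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position a new atom from three reference atoms (NeRF construction)."""
    angle = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.cos(dih) * np.sin(angle),
                  bond * np.sin(dih) * np.sin(angle)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_ideal_peptide(spec: SyntheticSpec,
                        dihedrals=None) -> Model:
    """Single ideal-geometry model for the spec's sequence and ss string.

    ``dihedrals`` optionally overrides the per-residue (φ, ψ) pairs (an
    entry of None falls back to the ss-string value) — handy for building
    turn/hairpin fixtures with explicit geometry.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.sequence)
    for attempt in range(20):
        coords = _build_backbone(spec, rng, dihedrals)
        if coords is not None:
            break
    else:
        raise ValidationError("could not build a self-avoiding coil chain")

    sites: list[AtomSite] = []
    xyz: list[np.ndarray] = []
    numbers = spec.residue_numbers()
    for i in range(n):
        resname = ONE_TO_THREE[spec.sequence[i].upper()]
        for atom in ("N", "CA", "C", "O", "CB"):
            if atom == "CB" and resname == "GLY":
                continue
            sites.append(AtomSite(spec.chain_id, numbers[i], resname, atom))
            xyz.append(coords[i][atom])
    return Model(sites, np.array(xyz), "1")


def _build_backbone(spec: SyntheticSpec, rng,
                    override=None) -> list[dict] | None:
    n = len(spec.sequence)
    dihedrals = []
    for i, cls in enumerate(spec.ss_string):
        if override is not None and override[i] is not None:
            dihedrals.append(tuple(override[i]))
        elif cls in CLASS_DIHEDRALS:
            dihedrals.append(CLASS_DIHEDRALS[cls])
        else:
            dihedrals.append((rng.uniform(*COIL_PHI_RANGE),
                              rng.uniform(*COIL_PSI_RANGE)))

    res: list[dict] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    C = _place(np.array([0.0, 1.0, 0.0]), N, CA, BOND_CA_C, ANGLE_N_CA_C,
               dihedrals[0][0])
    res.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n):
        phi_next = dihedrals[i][0]
        psi_prev = dihedrals[i - 1][1]
        prev = res[-1]
        N_i = _place(prev["N"], prev["CA"], prev["C"], BOND_C_N,
                     ANGLE_CA_C_N, psi_prev)
        CA_i = _place(prev["CA"], prev["C"], N_i, BOND_N_CA,
                      ANGLE_C_N_CA, OMEGA)
        C_i = _place(prev["C"], N_i, CA_i, BOND_CA_C, ANGLE_N_CA_C, phi_next)
        # carbonyl O anti to the next amide nitrogen: dihedral psi + 180
        prev["O"] = _place(prev["N"], prev["CA"], prev["C"], BOND_C_O,
                           ANGLE_CA_C_O, psi_prev + 180.0)
        res.append({"N": N_i, "CA": CA_i, "C": C_i})
    last = res[-1]
    last["O"] = _place(last["N"], last["CA"], last["C"], BOND_C_O,
                       ANGLE_CA_C_O, dihedrals[-1][1] + 180.0)
    for i, r in enumerate(res):
        r["CB"] = _place(r["N"], r["C"], r["CA"], BOND_CA_CB,
                         ANGLE_C_CA_CB, DIHEDRAL_N_C_CA_CB)

    # minimal self-avoidance check over non-neighbouring Cα pairs
    ca = np.array([r["CA"] for r in res])
    if n > 4:
        d = np.linalg.norm(ca[None, :, :] - ca[:, None, :], axis=-1)
        mask = np.triu(np.ones((n, n), bool), k=3)
        if np.any(d[mask] < MIN_CLASH_DIST):
            return None
    return res


def perturb_ensemble(model: Model, spec: SyntheticSpec) -> StructureEnsemble:
    """n_models noisy copies: σ = noise_core inside core_range, else noise_tail."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.core_range if spec.core_range is not None else (None, None)
    sigma = np.array([
        spec.noise_core if lo is not None and lo <= s.residue_number <= hi
        else (spec.noise_tail if lo is not None else spec.noise_core)
        for s in model.sites
    ])
    coords = np.stack([
        model.coords + rng.normal(0.0, 1.0, model.coords.shape) * sigma[:, None]
        for _ in range(spec.n_models)
    ])
    return StructureEnsemble(list(model.sites), coords,
                             [str(i + 1) for i in range(spec.n_models)])


def simulate_shifts(spec: SyntheticSpec,
                    rc: pd.DataFrame | None = None,
                    offsets: dict[str, tuple[float, float]] | None = None,
                    noise_ppm: float = 0.0,
                    uncertainty_ppm: float = 0.3) -> pd.DataFrame:
    """Shift table = random coil + class offset + Gaussian noise (seeded)."""
    if rc is None:
        rc = load_random_coil_table()
    if offsets is None:
        offsets = DEFAULT_SHIFT_OFFSETS
    rng = np.random.default_rng(spec.seed)
    rows = []
    for num, letter, cls in zip(spec.residue_numbers(), spec.sequence.upper(),
                                spec.ss_string):
        resname = ONE_TO_THREE[letter]
        d_ca, d_cb = offsets[cls]
        for atom, offset in (("CA", d_ca), ("CB", d_cb)):
            if atom == "CB" and resname == "GLY":
                continue
            base = rc.loc[resname, atom]
            noise = rng.normal(0.0, noise_ppm) if noise_ppm > 0 else 0.0
            rows.append({"chain": spec.chain_id, "residue": num,
                         "resname": resname, "atom": atom,
                         "shift": float(base) + offset + noise,
                         "uncertainty": uncertainty_ppm})
    return pd.DataFrame(rows)


def simulate_hetex(kex, r1=1.5, i_eq=1.0,
                   delays=DEFAULT_DELAYS,
                   water: float | dict[float, float] = 1.0,
                   noise_frac: float = 0.0,
                   seed: int = 0,
                   chain_id: str = "A",
                   residues=None) -> IntensityTable:
    """Saturation-transfer intensity pairs from the shared forward model.

    ``kex`` (and optionally ``r1``, ``i_eq``) may be scalars or
    per-residue arrays; multiplicative Gaussian noise of fractional size
    ``noise_frac`` is applied to every intensity.
    """
    kex = np.atleast_1d(np.asarray(kex, float))
    n = len(kex)
    r1 = np.broadcast_to(np.asarray(r1, float), (n,))
    i_eq = np.broadcast_to(np.asarray(i_eq, float), (n,))
    if residues is None:
        residues = np.arange(1, n + 1)
    rng = np.random.default_rng(seed)

    def water_at(d):
        return water.get(d, 1.0) if isinstance(water, dict) else float(water)

    rows = []
    for i, resnum in enumerate(residues):
        for d in delays:
            for condition in ("saturated", "unsaturated"):
                val = float(hetex_intensity(
                    d, kex[i], r1[i], i_eq[i], water=water_at(d),
                    saturated=(condition == "saturated")))
                if noise_frac > 0:
                    val *= 1.0 + rng.normal(0.0, noise_frac)
                rows.append({"chain": chain_id, "residue": int(resnum),
                             "condition": condition, "delay": d,
                             "intensity": val})
    water_df = pd.DataFrame({"delay": list(delays),
                             "water_intensity": [water_at(d) for d in delays]})
    return IntensityTable(pd.DataFrame(rows), water_df)


def simulate_hd_observations(last_seen: dict[tuple[str, int], float | None],
                             timepoints=(11.0, 39.0, 67.0, 431.0)
                             ) -> dict[tuple[str, int], set[float]]:
    """Observation sets from ground-truth 'last identifiable' timepoints.

    ``last_seen[residue] = None`` means the amide exchanged before the
    first spectrum (fast).
    """
    grid = sorted(timepoints)
    return {
        key: set() if last is None else {t for t in grid if t <= last}
        for key, last in last_seen.items()
    }


def simulate_score_table(n: int, seed: int = 0,
                         sequence: str = "AEAAIKKFFEAAGKLVEAA",
                         ss_string: str = "CHHHHHHHHHHHHHHHHHC"
                         ) -> tuple[pd.DataFrame, StructureEnsemble]:
    """Seeded (energy, chi2) score table with matching perturbed coordinates.

    A latent per-model quality q ∈ [0, 1] drives energy, shift agreement
    and coordinate noise together, so low-energy models also sit close to
    the reference — mirroring the funnel a fragment-assembly pool shows.
    Requires n >= 20 so the two-stage 20-then-10 selection is exercisable.
    """
    if n < 20:
        raise ValidationError("need n >= 20 models")
    rng = np.random.default_rng(seed)
    base_spec = SyntheticSpec(sequence=sequence, ss_string=ss_string,
                              n_models=1, seed=seed)
    base = build_ideal_peptide(base_spec)

    q = rng.uniform(0.0, 1.0, n)
    e_rosetta = -350.0 + 150.0 * q + rng.normal(0.0, 10.0, n)
    chi2 = np.clip(200.0 + 400.0 * q + rng.normal(0.0, 20.0, n), 0.0, None)
    sigma = 0.3 + 3.0 * q
    coords = np.stack([
        base.coords + rng.normal(0.0, sigma[i], base.coords.shape)
        for i in range(n)
    ])
    ids = [f"m{i+1:04d}" for i in range(n)]
    ensemble = StructureEnsemble(list(base.sites), coords, ids)
    scores = pd.DataFrame({"model_id": ids, "e_rosetta": e_rosetta,
                           "chi2": chi2})
    return scores, ensemble
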