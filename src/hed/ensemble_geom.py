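"""Ensemble geometry and flexibility descriptors.

Covers rigid-body superposition (Kabsch), per-residue Cα RMSF over a
superposed ensemble, the local bend metric d(Cα_{i-4}, Cα_{i+4}) — about
11–12 Å inside an α-helix, ~28 Å in an extended strand, intermediate where
a chain bends back on itself — and Shrake–Rupley backbone accessible
surface area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import SelectionError, ValidationError
from .io import Model, StructureEnsemble

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: van der Waals radii, Å
VDW_RADII = {"N": 1.55, "C": 1.70, "O": 1.52, "S": 1.80}
PROBE_RADIUS = 1.4


# ---------------------------------------------------------------------------
# selections


def parse_selection(text: str) -> set[tuple[str, int]]:
    """Parse ``"A:27-96,B:38-125"`` into a set of (chain, residue) keys."""
    keys: set[tuple[str, int]] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            chain, span = part.split(":")
            # a "-" after position 0 separates the range; a leading one is a sign
            sep = span.find("-", 1)
            if sep == -1:
                lo = hi = int(span)
            else:
                lo, hi = int(span[:sep]), int(span[sep + 1:])
            keys.update((chain, r) for r in range(lo, hi + 1))
        except (ValueError, TypeError) as exc:
            raise SelectionError(f"cannot parse selection part {part!r}") from exc
    if not keys:
        raise SelectionError("empty selection")
    return keys


def _ca_pairs(mobile: Model, reference: Model,
              selection: set[tuple[str, int]] | None) -> tuple[np.ndarray, np.ndarray]:
    mob_idx = mobile.atom_index()
    ref_idx = reference.atom_index()
    keys = sorted(
        {(c, r) for (c, r, a) in mob_idx if a == "CA"}
        & {(c, r) for (c, r, a) in ref_idx if a == "CA"}
    )
    if selection is not None:
        keys = [k for k in keys if k in selection]
    mob = np.array([mobile.coords[mob_idx[(c, r, "CA")]] for c, r in keys])
    ref = np.array([reference.coords[ref_idx[(c, r, "CA")]] for c, r in keys])
    return mob, ref


# ---------------------------------------------------------------------------
# superposition


@dataclass
class Superposition:
    """Rigid-body fit mapping mobile onto reference: x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid fit of point set ``mobile`` onto ``reference``.

    Raises :class:`SelectionError` for fewer than 3 points or a degenerate
    (collinear) configuration, where the rotation is underdetermined.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SelectionError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise SelectionError(f"need >= 3 point pairs, got {n}")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-8 * max(s[0], 1e-12):
        raise SelectionError("degenerate (collinear) selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = mu_r - rot @ mu_m
    fitted = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return Superposition(rot, trans, rmsd)


def superpose(mobile_model: Model, reference_model: Model,
              selection: set[tuple[str, int]] | str | None = None) -> Superposition:
    """Kabsch fit of one model onto another over selected Cα atoms."""
    if isinstance(selection, str):
        selection = parse_selection(selection)
    mob, ref = _ca_pairs(mobile_model, reference_model, selection)
    if len(mob) < 3:
        raise SelectionError(f"selection resolves to {len(mob)} Cα pairs (< 3)")
    return kabsch(mob, ref)


def ca_rmsd(mobile_model: Model, reference_model: Model,
            selection: set[tuple[str, int]] | str | None = None) -> float:
    return superpose(mobile_model, reference_model, selection).rmsd


# ---------------------------------------------------------------------------
# RMSF


def ca_rmsf(ensemble: StructureEnsemble,
            align_selection: set[tuple[str, int]] | str | None = None,
            reference: str = "mean",
            n_iter: int = 2) -> pd.DataFrame:
    """Per-residue Cα root-mean-square fluctuation over a superposed ensemble.

    With ``reference="mean"`` (default) the models are aligned iteratively
    to their mean structure (order-invariant); ``reference="first"``
    aligns everything onto model 1 instead.  RMSF(i) =
    sqrt(mean_m |Cα_i^m − <Cα_i>|²) after alignment.
    """
    if isinstance(align_selection, str):
        align_selection = parse_selection(align_selection)
    ca_keys = [s.residue_key for s in ensemble.sites if s.atom_name == "CA"]
    ca_rows = [i for i, s in enumerate(ensemble.sites) if s.atom_name == "CA"]
    if not ca_rows:
        raise SelectionError("ensemble has no CA atoms")
    coords = ensemble.coords[:, ca_rows, :].copy()  # (m, n_ca, 3)
    if align_selection is None:
        fit_cols = np.arange(len(ca_keys))
    else:
        fit_cols = np.array([i for i, k in enumerate(ca_keys) if k in align_selection])
    if len(fit_cols) < 3:
        raise SelectionError("alignment selection resolves to < 3 Cα atoms")

    if ensemble.n_models == 1:
        logger.warning("single-model ensemble: RMSF is identically zero")
        rmsf = np.zeros(len(ca_keys))
    else:
        ref = coords[0, fit_cols]
        rounds = 1 if reference == "first" else max(1, n_iter)
        for it in range(rounds):
            for m in range(coords.shape[0]):
                sup = kabsch(coords[m, fit_cols], ref)
                coords[m] = sup.apply(coords[m])
            if reference == "first":
                break
            ref = coords[:, fit_cols].mean(axis=0)
        mean = coords.mean(axis=0)
        rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))

    return pd.DataFrame({
        "chain": [k[0] for k in ca_keys],
        "residue": [k[1] for k in ca_keys],
        "rmsf": rmsf,
    })


# ---------------------------------------------------------------------------
# window distance


def ca_window_distance(obj: Model | StructureEnsemble,
                       half_window: int = 4) -> pd.DataFrame:
    """d(Cα_{i-w}, Cα_{i+w}) per interior residue (ensemble mean for ensembles).

    Residues are matched by number within each chain; rows exist only where
    both flanking residues carry a Cα.
    """
    ensemble = obj if isinstance(obj, StructureEnsemble) else \
        StructureEnsemble(obj.sites, obj.coords[None, :, :], [obj.model_id])
    w = half_window
    ca = {(s.chain_id, s.residue_number): i
          for i, s in enumerate(ensemble.sites) if s.atom_name == "CA"}
    rows = []
    for (chain, num), _ in sorted(ca.items(), key=lambda kv: kv[1]):
        lo, hi = ca.get((chain, num - w)), ca.get((chain, num + w))
        if lo is None or hi is None:
            continue
        d = np.linalg.norm(ensemble.coords[:, hi] - ensemble.coords[:, lo], axis=1)
        rows.append({"chain": chain, "residue": num, "d_window": float(d.mean())})
    return pd.DataFrame(rows, columns=["chain", "residue", "d_window"])


# ---------------------------------------------------------------------------
# accessible surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _radius_of(atom_name: str) -> float | None:
    name = atom_name.strip().lstrip("0123456789")
    return VDW_RADII.get(name[:1])


def atom_asa(coords: np.ndarray, radii: np.ndarray,
             probe_radius: float = PROBE_RADIUS,
             n_points: int = 960) -> np.ndarray:
    """Shrake–Rupley per-atom solvent accessible surface area, Å²."""
    coords = np.asarray(coords, float)
    n_atoms = len(coords)
    pts = _sphere_points(n_points)
    out = np.zeros(n_atoms)
    ext = radii + probe_radius
    for i in range(n_atoms):
        ri = ext[i]
        sphere = coords[i] + ri * pts
        accessible = np.ones(n_points, bool)
        d2 = np.sum((coords - coords[i]) ** 2, axis=1)
        near = np.flatnonzero((d2 < (ri + ext) ** 2) & (np.arange(n_atoms) != i))
        for j in near:
            accessible &= np.sum((sphere - coords[j]) ** 2, axis=1) > ext[j] ** 2
            if not accessible.any():
                break
        out[i] = 4.0 * np.pi * ri ** 2 * accessible.mean()
    return out


def backbone_asa(model: Model,
                 probe_radius: float = PROBE_RADIUS,
                 n_points: int = 960) -> pd.DataFrame:
    """Per-residue backbone (N, Cα, C, O) accessible surface area.

    All heavy atoms of the model occlude; hydrogens are ignored.  The
    ``relative`` column divides by a per-residue-type Gly-X-Gly-style
    maximum computed from an extended tripeptide, so fully solvent-exposed
    tails score near 1.
    """
    keep = [(i, s) for i, s in enumerate(model.sites)
            if _radius_of(s.atom_name) is not None]
    coords = np.array([model.coords[i] for i, _ in keep])
    radii = np.array([_radius_of(s.atom_name) for _, s in keep])
    asa = atom_asa(coords, radii, probe_radius, n_points)

    per_res: dict[tuple[str, int], float] = {}
    names = model.residue_names()
    for (_, site), a in zip(keep, asa):
        if site.atom_name in BACKBONE_ATOMS:
            per_res[site.residue_key] = per_res.get(site.residue_key, 0.0) + a

    order: dict[tuple[str, int], int] = {}
    for s in model.sites:
        order.setdefault(s.residue_key, len(order))
    rows = []
    for key in sorted(per_res, key=order.__getitem__):
        ref = _gxg_reference(names[key], probe_radius, n_points)
        rows.append({
            "chain": key[0], "residue": key[1], "resname": names[key],
            "backbone_asa": per_res[key],
            "relative": per_res[key] / ref if ref > 0 else np.nan,
        })
    return pd.DataFrame(rows)


@lru_cache(maxsize=None)
def _gxg_reference(resname: str, probe_radius: float, n_points: int) -> float:
    """Backbone ASA of residue X in an extended Gly-X-Gly tripeptide."""
    from .synthetic import THREE_TO_ONE, SyntheticSpec, build_ideal_peptide

    one = THREE_TO_ONE.get(resname.upper(), "A")
    spec = SyntheticSpec(sequence=f"G{one}G", ss_string="EEE", seed=0)
    tri = build_ideal_peptide(spec)
    df = backbone_asa_raw(tri, probe_radius, n_points)
    return float(df.loc[df["residue"] == 2, "backbone_asa"].iloc[0])


def backbone_asa_raw(model: Model, probe_radius: float,
                     n_points: int) -> pd.DataFrame:
    """Backbone ASA without the relative column (used for references)."""
    keep = [(i, s) for i, s in enumerate(model.sites)
            if _radius_of(s.atom_name) is not None]
    coords = np.array([model.coords[i] for i, _ in keep])
    radii = np.array([_radius_of(s.atom_name) for _, s in keep])
    asa = atom_asa(coords, radii, probe_radius, n_points)
    per_res: dict[tuple[str, int], float] = {}
    for (_, site), a in zip(keep, asa):
        if site.atom_name in BACKBONE_ATOMS:
            per_res[site.residue_key] = per_res.get(site.residue_key, 0.0) + a
    return pd.DataFrame(
        [{"chain": c, "residue": r, "backbone_asa": v}
         for (c, r), v in per_res.items()]
    )
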