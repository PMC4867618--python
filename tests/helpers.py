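"""Shared independent oracles and fixture builders for the test suite.

Everything here deliberately avoids the package's own code paths where it
serves as a cross-check: the quaternion superposition is Horn's method
(eigenvector of the 4x4 profile matrix), the secondary-structure reference
is mdtraj's DSSP, and the selection oracle is a plain enumerate-and-sort.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np

from hed.io import Model, StructureEnsemble, write_ensemble


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal rigid-fit RMSD via Horn's quaternion method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    sxx = x.T @ y
    a = np.array([
        [sxx[0, 0] + sxx[1, 1] + sxx[2, 2], sxx[1, 2] - sxx[2, 1],
         sxx[2, 0] - sxx[0, 2], sxx[0, 1] - sxx[1, 0]],
        [sxx[1, 2] - sxx[2, 1], sxx[0, 0] - sxx[1, 1] - sxx[2, 2],
         sxx[0, 1] + sxx[1, 0], sxx[2, 0] + sxx[0, 2]],
        [sxx[2, 0] - sxx[0, 2], sxx[0, 1] + sxx[1, 0],
         -sxx[0, 0] + sxx[1, 1] - sxx[2, 2], sxx[1, 2] + sxx[2, 1]],
        [sxx[0, 1] - sxx[1, 0], sxx[2, 0] + sxx[0, 2],
         sxx[1, 2] + sxx[2, 1], -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]],
    ])
    lam = np.linalg.eigvalsh(a)[-1]
    e0 = float(np.sum(x ** 2) + np.sum(y ** 2))
    msd = max(0.0, (e0 - 2.0 * lam)) / len(x)
    return float(np.sqrt(msd))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def mdtraj_ss(model: Model) -> str:
    """Reference DSSP string (mdtraj), blanks mapped to C."""
    import warnings

    import mdtraj as md

    fd, path = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    try:
        write_ensemble(StructureEnsemble(model.sites, model.coords[None],
                                         ["1"]), path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            codes = md.compute_dssp(md.load(path), simplified=False)[0]
    finally:
        os.remove(path)
    return "".join(c if c != " " else "C" for c in codes)


def brute_force_select(scores, rmsd_by_id, n_energy=20, n_final=10, c=0.25):
    """Enumerate-and-sort oracle for the two-stage selection.

    ``scores``: list of (model_id, e_rosetta, chi2); ``rmsd_by_id`` maps id
    to Cα-RMSD against the lowest-E_CS model (computed by the caller with
    an independent fit).  Pure-python re-statement of the rule.
    """
    rows = [(mid, e + c * x2) for (mid, e, x2) in scores]
    shortlist = sorted(rows, key=lambda r: (r[1], r[0]))[:n_energy]
    final = sorted(shortlist, key=lambda r: (rmsd_by_id[r[0]], r[1], r[0]))
    return [mid for mid, _ in final[:n_final]]
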