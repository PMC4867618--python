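"""Geometry-based secondary-structure assignment and ensemble propensities.

This is a self-contained Kabsch–Sander implementation.  A backbone
hydrogen bond between donor NH(i) and acceptor C=O(j) is scored with the
electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and accepted when E < -0.5 kcal/mol.  From the bond list:

* n-turn at i when NH(i+n) bonds CO(i), n in 3, 4, 5;
* α-helix (H): two consecutive 4-turns at i-1 and i mark residues i..i+3;
* 3₁₀ helix (G): two consecutive 3-turns mark i..i+2;
* bridges (parallel/antiparallel) from the classic bond patterns; bridges
  that stack into ladders give extended strand (E), isolated ones B;
* turn (T): any residue spanned by an n-turn; bend (S): virtual-bond angle
  CA(i-2)->CA(i)->CA(i+2) above 70 degrees.

Overlaps resolve by the priority H > G > E > B > T > S > C.  Amide
hydrogens are built geometrically (N + 1.0 Å along C'(i-1)−O(i-1)) when the
file has none; proline never donates.  Chains are split at any C(i)-N(i+1)
distance above 2.5 Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Model, StructureEnsemble

logger = logging.getLogger(__name__)

SS_CLASSES = ("H", "G", "E", "B", "T", "S", "C")

_Q = 0.084 * 332.0        # kcal/mol * Å, Kabsch–Sander coupling constant
_HBOND_CUTOFF = -0.5      # kcal/mol
_CA_CUTOFF = 9.0          # Å, pair prescreen
_BREAK_DIST = 2.5         # Å, C(i)-N(i+1) above this = chain break
_BEND_ANGLE = 70.0        # degrees
_MIN_E = -9.9             # clamp for clashing geometries


@dataclass
class _Residue:
    chain: str
    number: int
    name: str
    atoms: dict
    segment: int = -1

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))


def _collect_residues(model: Model) -> list[_Residue]:
    residues = []
    names = model.residue_names()
    for key, atoms in model.residues().items():
        residues.append(_Residue(key[0], key[1], names[key], dict(atoms)))
    return residues


def _segment(residues: list[_Residue]) -> None:
    """Assign contiguous-segment ids; break on chain change or C-N gap."""
    seg = 0
    for i, res in enumerate(residues):
        if i > 0:
            prev = residues[i - 1]
            linked = (
                prev.chain == res.chain
                and "C" in prev.atoms and "N" in res.atoms
                and np.linalg.norm(prev.atoms["C"] - res.atoms["N"]) < _BREAK_DIST
            )
            if not linked:
                seg += 1
        res.segment = seg


def _build_hydrogens(residues: list[_Residue]) -> None:
    for i, res in enumerate(residues):
        if res.name == "PRO" or "N" not in res.atoms:
            continue
        if any(h in res.atoms for h in ("H", "HN")):
            res.atoms.setdefault("H", res.atoms.get("H", res.atoms.get("HN")))
            continue
        if i == 0 or residues[i - 1].segment != res.segment:
            continue
        prev = residues[i - 1]
        if "C" not in prev.atoms or "O" not in prev.atoms:
            continue
        direction = prev.atoms["C"] - prev.atoms["O"]
        norm = np.linalg.norm(direction)
        if norm > 0:
            res.atoms["H"] = res.atoms["N"] + direction / norm


def hbond_energy(donor: _Residue, acceptor: _Residue) -> float:
    """Kabsch–Sander electrostatic H-bond energy, kcal/mol."""
    n, h = donor.atoms["N"], donor.atoms["H"]
    c, o = acceptor.atoms["C"], acceptor.atoms["O"]
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return _MIN_E
    e = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, _MIN_E)


def _hbond_set(residues: list[_Residue]) -> set[tuple[int, int]]:
    """(donor_index, acceptor_index) pairs with E < cutoff."""
    donors = [i for i, r in enumerate(residues)
              if r.name != "PRO" and "N" in r.atoms and "H" in r.atoms]
    acceptors = [j for j, r in enumerate(residues)
                 if "C" in r.atoms and "O" in r.atoms]
    ca = {i: r.atoms["CA"] for i, r in enumerate(residues) if "CA" in r.atoms}
    bonds = set()
    for i in donors:
        for j in acceptors:
            if i == j:
                continue
            if i in ca and j in ca and np.linalg.norm(ca[i] - ca[j]) > _CA_CUTOFF:
                continue
            if hbond_energy(residues[i], residues[j]) < _HBOND_CUTOFF:
                bonds.add((i, j))
    return bonds


def assign_ss(model: Model) -> pd.Series:
    """Per-residue secondary-structure class for one model.

    Returns a Series indexed by (chain, residue_number) in file order with
    values from ``SS_CLASSES``.  Residues with incomplete backbones are
    assigned C with a warning.
    """
    residues = _collect_residues(model)
    if not residues:
        raise ValidationError("model has no residues")
    _segment(residues)
    _build_hydrogens(residues)

    incomplete = [r for r in residues if not r.has_backbone()]
    if incomplete:
        logger.warning("%d residues lack a full backbone; assigned C",
                       len(incomplete))

    hb = _hbond_set(residues)
    n_res = len(residues)

    def same_run(i: int, j: int) -> bool:
        """i..j are consecutive residues of one segment."""
        if not (0 <= i and j < n_res):
            return False
        return all(residues[k].segment == residues[i].segment
                   for k in range(i, j + 1))

    # n-turns: NH(i+n) -> CO(i)
    turn = {n: np.zeros(n_res, bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if same_run(i, i + n) and (i + n, i) in hb:
                turn[n][i] = True

    is_h = np.zeros(n_res, bool)
    is_g = np.zeros(n_res, bool)
    is_t = np.zeros(n_res, bool)
    for i in range(1, n_res):
        if turn[4][i - 1] and turn[4][i]:
            is_h[i:i + 4] = True
        if turn[3][i - 1] and turn[3][i]:
            is_g[i:i + 3] = True
    for n in (3, 4, 5):
        for i in np.flatnonzero(turn[n]):
            is_t[i + 1:i + n] = True

    # bridges: Hbond(a, b) below means CO(a) <- NH(b), i.e. (b, a) in hb
    def hbond(a: int, b: int) -> bool:
        return (b, a) in hb

    bridges: list[tuple[int, int, str]] = []
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or \
                   (hbond(j - 1, i) and hbond(i, j + 1))
            anti = (hbond(i, j) and hbond(j, i)) or \
                   (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
            if para:
                bridges.append((i, j, "P"))
            elif anti:
                bridges.append((i, j, "A"))

    bridge_set = set(bridges)
    is_e = np.zeros(n_res, bool)
    is_b = np.zeros(n_res, bool)
    for (i, j, kind) in bridges:
        if kind == "P":
            in_ladder = (i - 1, j - 1, "P") in bridge_set or \
                        (i + 1, j + 1, "P") in bridge_set
        else:
            in_ladder = (i - 1, j + 1, "A") in bridge_set or \
                        (i + 1, j - 1, "A") in bridge_set
        target = is_e if in_ladder else is_b
        target[i] = True
        target[j] = True
    is_b &= ~is_e

    # bends from the CA virtual-bond angle
    is_s = np.zeros(n_res, bool)
    for i in range(2, n_res - 2):
        if not same_run(i - 2, i + 2):
            continue
        if not all("CA" in residues[k].atoms for k in range(i - 2, i + 3)):
            continue
        u = residues[i].atoms["CA"] - residues[i - 2].atoms["CA"]
        v = residues[i + 2].atoms["CA"] - residues[i].atoms["CA"]
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom == 0:
            continue
        cosang = np.clip(np.dot(u, v) / denom, -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) > _BEND_ANGLE:
            is_s[i] = True

    classes = []
    for i, res in enumerate(residues):
        if not res.has_backbone():
            classes.append("C")
        elif is_h[i]:
            classes.append("H")
        elif is_g[i]:
            classes.append("G")
        elif is_e[i]:
            classes.append("E")
        elif is_b[i]:
            classes.append("B")
        elif is_t[i]:
            classes.append("T")
        elif is_s[i]:
            classes.append("S")
        else:
            classes.append("C")

    index = pd.MultiIndex.from_tuples(
        [(r.chain, r.number) for r in residues], names=["chain", "residue"]
    )
    return pd.Series(classes, index=index, name="ss")


def ensemble_propensity(ensemble: StructureEnsemble) -> pd.DataFrame:
    """Per-residue frequency of each class across the ensemble models.

    Rows are (chain, residue); columns are the seven classes; each row sums
    to 1 for residues present in every model.
    """
    counts: pd.DataFrame | None = None
    for model in ensemble:
        ss = assign_ss(model)
        onehot = pd.get_dummies(ss).reindex(columns=SS_CLASSES,
                                            fill_value=0).astype(float)
        counts = onehot if counts is None else counts.add(onehot, fill_value=0)
    assert counts is not None
    return counts / ensemble.n_models


def define_elements(profile: pd.DataFrame,
                    threshold: float = 0.8,
                    helix_classes: tuple[str, ...] = ("H", "G"),
                    strand_classes: tuple[str, ...] = ("E", "B"),
                    min_helix: int = 3,
                    min_strand: int = 2) -> pd.DataFrame:
    """Secondary-structure elements from a propensity profile.

    A residue belongs to a helix (strand) element when its summed helix
    (strand) class frequency strictly exceeds ``threshold``; maximal runs
    shorter than the class minimum are dropped.  Returns a DataFrame with
    columns ``class chain start end``.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    rows = []
    for kind, cls, min_len in (("helix", helix_classes, min_helix),
                               ("strand", strand_classes, min_strand)):
        mask = profile[list(cls)].sum(axis=1) > threshold
        for (chain, start, end) in _runs(mask):
            if end - start + 1 >= min_len:
                rows.append({"class": kind, "chain": chain,
                             "start": start, "end": end})
    out = pd.DataFrame(rows, columns=["class", "chain", "start", "end"])
    return out.sort_values(["chain", "start"]).reset_index(drop=True)


def _runs(mask: pd.Series) -> list[tuple[str, int, int]]:
    """Maximal runs of True over consecutive residue numbers per chain."""
    runs = []
    current = None  # (chain, start, prev)
    for (chain, resnum), flag in mask.items():
        if flag and current is not None and current[0] == chain \
                and resnum == current[2] + 1:
            current = (chain, current[1], resnum)
        else:
            if current is not None:
                runs.append(current)
                current = None
            if flag:
                current = (chain, resnum, resnum)
    if current is not None:
        runs.append(current)
    return runs
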