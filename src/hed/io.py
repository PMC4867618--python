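"""Readers and writers for structure ensembles and tabular NMR data.

Structures are handled through gemmi (PDB and mmCIF).  An ensemble is a
multi-MODEL file whose models all share one topology; coordinates are kept
in a single ``(n_models, n_atoms, 3)`` array so downstream numerics never
re-match atoms.  Residue numbering is plain ``(chain_id, integer)`` —
negative numbers and zero are legal (histone constructs are commonly
numbered from cloning-tag residues such as Gly(-3) or Met0); insertion
codes are not supported.

Chemical shifts and amide intensities are plain pandas DataFrames with a
documented schema, validated on read:

* shift table columns: ``chain residue resname atom shift uncertainty``
* intensity table columns: ``chain residue condition delay intensity``

Atom types are normalized to the six backbone ASCII tokens
``HN HA N CA CB C`` (standing for HN, Hα, N, Cα, Cβ, C′).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical backbone atom-type tokens and accepted synonyms
ATOM_TYPES = ("HN", "HA", "N", "CA", "CB", "C")
ATOM_SYNONYMS = {
    "H": "HN", "HN": "HN",
    "HA": "HA", "HALPHA": "HA",
    "N": "N",
    "CA": "CA", "CALPHA": "CA",
    "CB": "CB", "CBETA": "CB",
    "C": "C", "C'": "C", "CO": "C",
}

SHIFT_COLUMNS = ["chain", "residue", "resname", "atom", "shift", "uncertainty"]
INTENSITY_COLUMNS = ["chain", "residue", "condition", "delay", "intensity"]
CONDITIONS = ("saturated", "unsaturated")


@dataclass(frozen=True)
class AtomSite:
    """Identity of one atom in the shared ensemble topology."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class Model:
    """One conformer: shared topology plus an ``(n_atoms, 3)`` coordinate block."""

    sites: list[AtomSite]
    coords: np.ndarray
    model_id: str = "1"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sites), 3):
            raise ValidationError(
                f"coordinate block {self.coords.shape} does not match "
                f"{len(self.sites)} atom sites"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        """(chain, residue_number, atom_name) -> row into coords."""
        return {
            (s.chain_id, s.residue_number, s.atom_name): i
            for i, s in enumerate(self.sites)
        }

    def residues(self) -> dict[tuple[str, int], dict[str, np.ndarray]]:
        """Residue-grouped coordinates, keyed (chain, number) -> {atom: xyz},
        in file order."""
        out: dict[tuple[str, int], dict[str, np.ndarray]] = {}
        for i, s in enumerate(self.sites):
            out.setdefault(s.residue_key, {})[s.atom_name] = self.coords[i]
        return out

    def residue_names(self) -> dict[tuple[str, int], str]:
        out: dict[tuple[str, int], str] = {}
        for s in self.sites:
            out.setdefault(s.residue_key, s.residue_name)
        return out


@dataclass
class StructureEnsemble:
    """Ordered conformer ensemble over one shared topology."""

    sites: list[AtomSite]
    coords: np.ndarray  # (n_models, n_atoms, 3)
    model_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValidationError("ensemble needs >= 1 model")
        if self.coords.shape[1:] != (len(self.sites), 3):
            raise ValidationError("coordinate block does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        if not self.model_ids:
            self.model_ids = [str(i + 1) for i in range(self.coords.shape[0])]
        if len(self.model_ids) != self.coords.shape[0]:
            raise ValidationError("model_ids length mismatch")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.sites)

    def model(self, i: int) -> Model:
        return Model(self.sites, self.coords[i], self.model_ids[i])

    def __iter__(self) -> Iterator[Model]:
        for i in range(self.n_models):
            yield self.model(i)

    @classmethod
    def from_models(cls, models: Sequence[Model]) -> "StructureEnsemble":
        ref = models[0]
        for m in models[1:]:
            _check_same_topology(ref.sites, m.sites, ref.model_id, m.model_id)
        return cls(
            sites=list(ref.sites),
            coords=np.stack([m.coords for m in models]),
            model_ids=[m.model_id for m in models],
        )


def _check_same_topology(a: list[AtomSite], b: list[AtomSite],
                         label_a: str, label_b: str) -> None:
    if len(a) != len(b):
        raise ValidationError(
            f"model {label_b} has {len(b)} atoms, model {label_a} has {len(a)}"
        )
    for i, (sa, sb) in enumerate(zip(a, b)):
        if sa != sb:
            raise ValidationError(
                f"model {label_b} atom {i} is "
                f"{sb.chain_id}/{sb.residue_number}/{sb.atom_name}, expected "
                f"{sa.chain_id}/{sa.residue_number}/{sa.atom_name} "
                f"(first discrepancy)"
            )


# ---------------------------------------------------------------------------
# structures


def _sites_from_gemmi_model(model: gemmi.Model) -> tuple[list[AtomSite], np.ndarray]:
    sites: list[AtomSite] = []
    xyz: list[tuple[float, float, float]] = []
    seen_altloc = False
    for chain in model:
        for res in chain:
            taken: set[str] = set()
            for atom in res:
                if atom.name in taken:  # keep first altloc only
                    seen_altloc = True
                    continue
                if atom.altloc not in ("", "\0", "A"):
                    seen_altloc = True
                    if atom.name not in taken:
                        # a non-primary altloc appearing first is still kept
                        pass
                taken.add(atom.name)
                sites.append(AtomSite(chain.name, res.seqid.num, res.name, atom.name))
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if seen_altloc:
        logger.warning("alternate locations present; kept the first per atom")
    return sites, np.asarray(xyz, dtype=float)


def read_ensemble(path: str | Path, format: str | None = None) -> StructureEnsemble:
    """Read a (possibly multi-MODEL) PDB or mmCIF file as an ensemble.

    All models must contain the same (chain, residue, atom) set in the same
    order; the first discrepancy is reported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown structure format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")

    models: list[Model] = []
    for gm in st:
        sites, xyz = _sites_from_gemmi_model(gm)
        if not sites:
            raise FormatError(f"{path}: model {gm.num} has no atoms")
        models.append(Model(sites, xyz, str(gm.num)))
    return StructureEnsemble.from_models(models)


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (3-decimal precision)."""
    if ensemble.n_models < 1 or ensemble.n_atoms < 1:
        raise ValidationError("refusing to write an empty ensemble")
    st = gemmi.Structure()
    st.name = "ensemble"
    for i, model in enumerate(ensemble):
        gm = gemmi.Model(i + 1)
        chain: gemmi.Chain | None = None
        res: gemmi.Residue | None = None
        for site, xyz in zip(model.sites, model.coords):
            if chain is None or chain.name != site.chain_id:
                if chain is not None:
                    if res is not None:
                        chain.add_residue(res)
                        res = None
                    gm.add_chain(chain)
                chain = gemmi.Chain(site.chain_id)
            if res is not None and (res.seqid.num != site.residue_number
                                    or res.name != site.residue_name):
                chain.add_residue(res)
                res = None
            if res is None:
                res = gemmi.Residue()
                res.name = site.residue_name
                res.seqid = gemmi.SeqId(site.residue_number, " ")
            atom = gemmi.Atom()
            atom.name = site.atom_name
            atom.element = gemmi.Element(_element_of(site.atom_name))
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        if res is not None and chain is not None:
            chain.add_residue(res)
        if chain is not None:
            gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name[1:]
    return {"N": "N", "C": "C", "O": "O", "S": "S", "H": "H"}.get(name[:1], "C")


# ---------------------------------------------------------------------------
# shift tables


def normalize_atom_type(name: str) -> str | None:
    """Map an atom-name synonym to a canonical token, or None if unknown."""
    return ATOM_SYNONYMS.get(name.strip().upper().replace("′", "'"))


def validate_shift_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"shift table lacks columns {missing}")
    df = df[SHIFT_COLUMNS].copy()
    df["residue"] = df["residue"].astype(int)
    df["shift"] = df["shift"].astype(float)
    df["uncertainty"] = pd.to_numeric(df["uncertainty"], errors="coerce")
    if not np.all(np.isfinite(df["shift"])):
        raise ValidationError("non-finite chemical shift")
    bad_sigma = df["uncertainty"].notna() & (df["uncertainty"] <= 0)
    if bad_sigma.any():
        raise ValidationError("uncertainty must be > 0 where present")
    dup = df.duplicated(subset=["chain", "residue", "atom"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate shift row for ({row['chain']}, {row['residue']}, "
            f"{row['atom']})"
        )
    return df.reset_index(drop=True)


def read_shift_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read chemical shifts from a TSV file or a minimal NMR-STAR subset.

    Rows with unrecognized atom types are skipped with a warning; duplicate
    (chain, residue, atom) rows raise :class:`ValidationError`.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        df = df.rename(columns={c: c.lower() for c in df.columns})
    elif dialect == "nmrstar-minimal":
        df = _read_nmrstar_shifts(path)
    else:
        raise FormatError(f"unknown shift-table dialect {dialect!r}")
    if "uncertainty" not in df.columns:
        df["uncertainty"] = np.nan

    atoms = df["atom"].astype(str).map(normalize_atom_type)
    unknown = atoms.isna()
    if unknown.any():
        skipped = sorted(set(df.loc[unknown, "atom"].astype(str)))
        logger.warning("skipping %d rows with unknown atom types: %s",
                       int(unknown.sum()), ", ".join(skipped))
    df = df.loc[~unknown].copy()
    df["atom"] = atoms[~unknown]
    return validate_shift_table(df)


def _read_nmrstar_shifts(path: Path) -> pd.DataFrame:
    """Minimal NMR-STAR reader: the ``_Atom_chem_shift`` loop only.

    Understands both version-3 dotted tags and the bare tag names used by
    older depositions; this is deliberately not a STAR grammar.
    """
    tag_map = {
        "comp_index_id": "residue", "seq_id": "residue",
        "comp_id": "resname",
        "atom_id": "atom",
        "val": "shift", "chem_shift_value": "shift",
        "val_err": "uncertainty", "chem_shift_value_error": "uncertainty",
        "auth_asym_id": "chain", "entity_assembly_id": "chain",
    }
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    collecting = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "loop_":
            in_loop, collecting, tags = True, False, []
            continue
        if in_loop and line.startswith("_"):
            if collecting:  # a new tag block after data rows: loop ended
                in_loop = False
            else:
                tag = line.split(".")[-1].lstrip("_").lower()
                tags.append(tag)
            continue
        if in_loop and line in ("stop_",):
            if rows:
                break
            in_loop = False
            continue
        if in_loop and tags:
            if "atom_id" not in tags and not any(t in tag_map for t in tags):
                in_loop = False
                continue
            collecting = True
            rows.append(line.split())
    if not rows or not tags:
        raise FormatError(f"{path}: no atom chemical-shift loop found")
    width = len(tags)
    data = [r for r in rows if len(r) == width]
    df = pd.DataFrame(data, columns=tags)
    df = df.rename(columns={k: v for k, v in tag_map.items() if k in df.columns})
    if "chain" not in df.columns:
        df["chain"] = "A"
    if "uncertainty" not in df.columns:
        df["uncertainty"] = np.nan
    for col in ("shift", "uncertainty"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    keep = [c for c in SHIFT_COLUMNS if c in df.columns]
    missing = [c for c in ("residue", "resname", "atom", "shift") if c not in keep]
    if missing:
        raise FormatError(f"{path}: shift loop lacks {missing}")
    return df[keep]


def write_shift_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_shift_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intensity tables


@dataclass
class IntensityTable:
    """Per-residue amide intensities vs relaxation delay, by condition.

    ``data`` columns: chain residue condition delay intensity.
    ``water`` (optional) columns: delay water_intensity — the measured water
    signal at each relaxation delay, normalized to its equilibrium value.
    """

    data: pd.DataFrame
    water: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"intensity table lacks columns {missing}")
        df = df[INTENSITY_COLUMNS].copy()
        df["residue"] = df["residue"].astype(int)
        df["delay"] = df["delay"].astype(float)
        df["intensity"] = df["intensity"].astype(float)
        if (df["delay"] < 0).any():
            raise ValidationError("negative relaxation delay")
        bad = ~df["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValidationError(
                f"unknown condition {df.loc[bad, 'condition'].iloc[0]!r}"
            )
        counts = df.groupby(["chain", "residue", "delay"])["condition"].nunique()
        sizes = df.groupby(["chain", "residue", "delay", "condition"]).size()
        if (sizes > 1).any():
            raise ValidationError("duplicate (residue, delay, condition) rows")
        del counts
        self.data = df.reset_index(drop=True)
        if self.water is None:
            logger.warning("no water-intensity sidecar; assuming fully "
                           "relaxed water (fraction 1.0) without saturation")
        else:
            w = self.water
            if not {"delay", "water_intensity"}.issubset(w.columns):
                raise ValidationError(
                    "water sidecar needs columns delay, water_intensity"
                )
            self.water = w[["delay", "water_intensity"]].astype(float)

    def water_fraction(self, delay: float) -> float:
        if self.water is None:
            return 1.0
        w = self.water
        hit = w.loc[np.isclose(w["delay"], delay), "water_intensity"]
        return float(hit.iloc[0]) if len(hit) else 1.0

    def residues(self) -> list[tuple[str, int]]:
        return sorted(
            set(map(tuple, self.data[["chain", "residue"]].itertuples(index=False))),
            key=lambda k: (k[0], k[1]),
        )


def read_intensity_table(path: str | Path,
                         water_path: str | Path | None = None) -> IntensityTable:
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    water = None
    if water_path is not None:
        water = pd.read_csv(water_path, sep=r"\s+", comment="#")
        water = water.rename(columns={c: c.lower() for c in water.columns})
    return IntensityTable(df, water)


def write_intensity_table(table: IntensityTable, path: str | Path,
                          water_path: str | Path | None = None) -> None:
    table.data.to_csv(path, sep="\t", index=False)
    if table.water is not None and water_path is not None:
        table.water.to_csv(water_path, sep="\t", index=False)
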