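"""Readers and writers for residue-keyed tables and PDB coordinate files.

Residue tables are delimited text (comma or tab, autodetected) with one
header row, a mandatory ``residue`` column (integer sequence position),
an optional ``resname`` column (one-letter code) and arbitrary numeric
data columns; per-column uncertainties use the ``<col>_err`` suffix.
Structures are read with gemmi; one :class:`StructureModel` per MODEL
block, HETATM ignored, first alternate location kept, insertion codes
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ResidueTable",
    "StructureModel",
    "read_residue_table",
    "write_residue_table",
    "read_structure_models",
]

AA1 = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ResidueTable:
    """A residue-keyed numeric table (thin wrapper around a DataFrame).

    ``data`` always holds a ``residue`` column of unique integers;
    ``resname`` is optional. All remaining columns are float64.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "residue" not in self.data.columns:
            raise ValueError("residue column missing")
        res = self.data["residue"]
        dup = res[res.duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate residue {int(dup.iloc[0])}")
        if "resname" in self.data.columns:
            bad = set(self.data["resname"].astype(str)) - AA1
            if bad:
                raise ValueError(f"unknown residue name(s): {sorted(bad)}")
        for col in self.value_columns:
            if col.endswith("_err") and (self.data[col].dropna() < 0).any():
                raise ValueError(f"negative uncertainties in column {col}")

    @property
    def value_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("residue", "resname")]

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def read_residue_table(path: str | Path, required: Iterable[str] = ()) -> ResidueTable:
    """Read a delimited residue table; delimiter (comma/tab) autodetected.

    Rows whose numeric columns fail coercion are dropped and reported via
    the returned table's attrs (``n_bad_rows``).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: no data rows")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if "residue" not in df.columns:
        raise ValueError(f"{path}: residue column missing")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    df["residue"] = pd.to_numeric(df["residue"], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["residue"])
    df["residue"] = df["residue"].astype(int)
    for col in df.columns:
        if col in ("residue", "resname"):
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    table = ResidueTable(df.reset_index(drop=True))
    table.data.attrs["n_bad_rows"] = n0 - len(df)
    return table


def write_residue_table(table: ResidueTable, path: str | Path) -> None:
    """Write a residue table as CSV, lossless to 9 significant digits."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty table")
    table.data.to_csv(path, index=False, float_format="%.9g")


@dataclass
class StructureModel:
    """One conformer: parallel arrays of residue number, residue name
    (3-letter), atom name, element and coordinates in Angstrom."""

    model_index: int
    residue_numbers: np.ndarray
    residue_names: list[str]
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self._index = {
            (int(r), a): i
            for i, (r, a) in enumerate(zip(self.residue_numbers, self.atom_names))
        }

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residues(self) -> np.ndarray:
        return np.unique(self.residue_numbers)

    def atom(self, residue: int, name: str) -> np.ndarray | None:
        """Coordinates of one atom, or None if absent."""
        i = self._index.get((residue, name))
        return None if i is None else self.coords[i]

    def select(self, residues: Iterable[int], atom_names: Iterable[str]) -> np.ndarray:
        """Stacked coordinates for a residue range and atom set; raises if
        any requested atom is missing (used for superposition)."""
        rows = []
        for r in residues:
            for a in atom_names:
                xyz = self.atom(int(r), a)
                if xyz is None:
                    raise KeyError(f"atom {a} of residue {r} missing")
                rows.append(xyz)
        return np.array(rows)


def read_structure_models(path: str | Path) -> list[StructureModel]:
    """Read a PDB file into one StructureModel per MODEL block.

    HETATM records are ignored; for alternate locations the first is
    kept; insertion codes are ignored.
    """
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    models: list[StructureModel] = []
    for i, model in enumerate(st):
        nums, rnames, anames, elems, xyz = [], [], [], [], []
        for chain in model:
            for res in chain:
                if res.het_flag == "H":
                    continue
                seen: set[str] = set()
                for atom in res:
                    if atom.name in seen:  # keep first altloc only
                        continue
                    seen.add(atom.name)
                    nums.append(res.seqid.num)
                    rnames.append(res.name)
                    anames.append(atom.name)
                    elems.append(atom.element.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if nums:
            models.append(StructureModel(
                model_index=i + 1,
                residue_numbers=np.array(nums, dtype=int),
                residue_names=rnames,
                atom_names=anames,
                elements=elems,
                coords=np.array(xyz, dtype=float),
            ))
    if not models:
        raise ValueError(f"{path}: no protein atoms")
    return models


def write_structure_model(model: StructureModel, path: str | Path) -> None:
    """Write a single model as minimal PDB (for round-trip tests and CLI)."""
    lines = []
    for i in range(model.n_atoms):
        name = model.atom_names[i]
        pad = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = model.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d} {pad:<4s} {model.residue_names[i]:>3s} A"
            f"{int(model.residue_numbers[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{model.elements[i]:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_structure_models(models: list[StructureModel], path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file."""
    chunks = []
    for m in models:
        chunks.append(f"MODEL     {m.model_index:4d}")
        body = []
        for i in range(m.n_atoms):
            name = m.atom_names[i]
            pad = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = m.coords[i]
            body.append(
                f"ATOM  {i + 1:5d} {pad:<4s} {m.residue_names[i]:>3s} A"
                f"{int(m.residue_numbers[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{m.elements[i]:>2s}"
            )
        chunks.extend(body)
        chunks.append("ENDMDL")
    chunks.append("END")
    Path(path).write_text("\n".join(chunks) + "\n")
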