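"""Ensemble I/O: multi-model PDB reading, selections, manifests, observable CSVs.

The interchange format for conformational ensembles is the multi-model PDB —
every MD package can export one — accompanied by a JSON manifest listing each
conformer's file, ligand state, frame spacing and production length. A
selection spec maps chains/residue ranges in those files onto the geometric
reference points of :class:`~fretforge.geometry.LabeledFrame`: the two
fluorescent modules (whose geometric centers define D) and each module's
Ser147 C-alpha-equivalent bead (which defines the dipole tip).

PDB coordinates are Angstrom; everything downstream of this module is nm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .ensemble import TrajectoryRecord
from .geometry import LabeledFrame

__all__ = [
    "ResidueRange",
    "SelectionSpec",
    "SelectionError",
    "ManifestEntry",
    "EnsembleManifest",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "manifest_totals",
    "write_observables",
    "read_observables",
]

ANGSTROM_PER_NM = 10.0

#: Default recording interval assumed when a manifest omits frame spacing.
DEFAULT_FRAME_SPACING_PS = 100.0


class SelectionError(ValueError):
    """A selector failed to resolve against the structure."""


@dataclass(frozen=True)
class ResidueRange:
    """Chain + inclusive residue interval, e.g. chain A residues 1-230."""

    chain: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.last < self.first:
            raise ValueError(f"residue range reversed: {self.first}-{self.last}")

    def mask(self, atoms: struc.AtomArray) -> np.ndarray:
        return (
            (atoms.chain_id == self.chain)
            & (atoms.res_id >= self.first)
            & (atoms.res_id <= self.last)
        )


@dataclass(frozen=True)
class SelectionSpec:
    """Maps structure-file content to the sensor's geometric reference points.

    ``donor_tip`` / ``acceptor_tip`` must resolve to exactly one atom (the
    Ser147 C-alpha of the fluorescent module, or its coarse-grained
    equivalent); ``tip_atom_names`` lists the accepted bead names since
    coarse-grained models name the backbone bead differently (e.g. "GC").
    """

    donor_module: ResidueRange
    acceptor_module: ResidueRange
    donor_tip: ResidueRange
    acceptor_tip: ResidueRange
    tip_atom_names: tuple[str, ...] = ("CA", "GC")
    rmsd_selection: Optional[ResidueRange] = None

    @classmethod
    def from_json(cls, path) -> "SelectionSpec":
        with open(path) as fh:
            d = json.load(fh)

        def rr(key):
            if key not in d or d[key] is None:
                return None
            e = d[key]
            return ResidueRange(e["chain"], int(e["first"]), int(e["last"]))

        return cls(
            donor_module=rr("donor_module"),
            acceptor_module=rr("acceptor_module"),
            donor_tip=rr("donor_tip"),
            acceptor_tip=rr("acceptor_tip"),
            tip_atom_names=tuple(d.get("tip_atom_names", ("CA", "GC"))),
            rmsd_selection=rr("rmsd_selection"),
        )

    def to_json(self, path) -> None:
        d = {
            k: asdict(v) if isinstance(v, ResidueRange) else v
            for k, v in asdict(self).items()
        }
        d["tip_atom_names"] = list(self.tip_atom_names)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    conformer_id: str
    state: str
    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS
    production_length_us: float = 10.0


@dataclass
class EnsembleManifest:
    """Collection of conformer entries making up a bound/free campaign."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.conformer_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate conformer_id(s) in manifest: {dupes}")
        for e in self.entries:
            if e.state not in ("bound", "free"):
                raise ValueError(f"invalid state {e.state!r} for {e.conformer_id}")

    @property
    def n_bound(self) -> int:
        return sum(1 for e in self.entries if e.state == "bound")

    @property
    def n_free(self) -> int:
        return sum(1 for e in self.entries if e.state == "free")

    @classmethod
    def from_json(cls, path) -> "EnsembleManifest":
        with open(path) as fh:
            d = json.load(fh)
        entries = []
        for e in d["entries"]:
            if "frame_spacing_ps" not in e:
                warnings.warn(
                    f"manifest entry {e.get('conformer_id')} lacks frame_spacing_ps; "
                    f"assuming the standard {DEFAULT_FRAME_SPACING_PS} ps recording interval"
                )
            entries.append(
                ManifestEntry(
                    path=e["path"],
                    conformer_id=e["conformer_id"],
                    state=e["state"],
                    frame_spacing_ps=float(
                        e.get("frame_spacing_ps", DEFAULT_FRAME_SPACING_PS)
                    ),
                    production_length_us=float(e.get("production_length_us", 10.0)),
                )
            )
        return cls(entries=entries)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"entries": [asdict(e) for e in self.entries]}, fh, indent=2)


def manifest_totals(manifest: EnsembleManifest) -> tuple[int, int, float]:
    """(n_bound, n_free, cumulative simulation time in ms).

    A standard campaign of 16 bound + 8 free conformers at 10 us each totals
    0.24 ms.
    """
    cumulative_ms = sum(e.production_length_us for e in manifest.entries) * 1e-3
    return manifest.n_bound, manifest.n_free, cumulative_ms


def _resolve_center(atoms: struc.AtomArray, sel: ResidueRange, label: str) -> np.ndarray:
    mask = sel.mask(atoms)
    if not mask.any():
        raise SelectionError(
            f"{label} selector (chain {sel.chain!r}, residues {sel.first}-{sel.last}) "
            f"matched no atoms"
        )
    # unweighted geometric center of the selected beads
    return atoms.coord[mask].mean(axis=0)


def _resolve_tip(
    atoms: struc.AtomArray, sel: ResidueRange, atom_names: Sequence[str], label: str
) -> np.ndarray:
    mask = sel.mask(atoms) & np.isin(atoms.atom_name, list(atom_names))
    n = int(mask.sum())
    if n != 1:
        raise SelectionError(
            f"{label} selector (chain {sel.chain!r}, residues {sel.first}-{sel.last}, "
            f"atom names {list(atom_names)}) matched {n} atoms; exactly 1 required"
        )
    return atoms.coord[mask][0]


def read_multimodel_pdb(
    path,
    selection: SelectionSpec,
    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS,
) -> list[LabeledFrame]:
    """Read a multi-model PDB into LabeledFrames via a selection spec.

    One frame per MODEL (a single-structure file yields one frame). Module
    centers are the unweighted mean of the selected bead coordinates;
    coordinates are converted Angstrom -> nm; frame times are assigned from
    ``frame_spacing_ps``.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure()  # AtomArrayStack, coords in Angstrom
    if stack.array_length() == 0:
        raise SelectionError(f"{path}: no atoms read")
    frames = []
    spacing_ns = frame_spacing_ps * 1e-3
    for i in range(stack.stack_depth()):
        atoms = stack[i]
        dc = _resolve_center(atoms, selection.donor_module, "donor_module")
        ac = _resolve_center(atoms, selection.acceptor_module, "acceptor_module")
        dt = _resolve_tip(atoms, selection.donor_tip, selection.tip_atom_names, "donor_tip")
        at = _resolve_tip(
            atoms, selection.acceptor_tip, selection.tip_atom_names, "acceptor_tip"
        )
        ca = None
        if selection.rmsd_selection is not None:
            mask = selection.rmsd_selection.mask(atoms) & np.isin(
                atoms.atom_name, list(selection.tip_atom_names)
            )
            if not mask.any():
                raise SelectionError("rmsd_selection matched no atoms")
            ca = atoms.coord[mask] / ANGSTROM_PER_NM
        frames.append(
            LabeledFrame(
                time=i * spacing_ns,
                donor_center=dc / ANGSTROM_PER_NM,
                donor_tip=dt / ANGSTROM_PER_NM,
                acceptor_center=ac / ANGSTROM_PER_NM,
                acceptor_tip=at / ANGSTROM_PER_NM,
                ca_coords=ca,
            )
        )
    return frames


def write_multimodel_pdb(path, stack: struc.AtomArrayStack) -> None:
    """Write an AtomArrayStack (coords in Angstrom) as a multi-model PDB."""
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Observable CSV round-trip
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("conformer_id", "state", "frame_spacing_ps")


def write_observables(path, record: TrajectoryRecord) -> None:
    """Write a per-frame observable table as CSV with a metadata header.

    Header lines are ``# key=value`` comments so the file stays a plain CSV.
    """
    with open(path, "w") as fh:
        fh.write(f"# conformer_id={record.conformer_id}\n")
        fh.write(f"# state={record.state}\n")
        fh.write(f"# frame_spacing_ps={record.frame_spacing_ps!r}\n")
        pd.DataFrame(
            {
                "time_ns": record.time_ns,
                "distance_nm": record.distance_nm,
                "kappa2": record.kappa2,
                "efficiency": record.efficiency,
            }
        ).to_csv(fh, index=False, float_format="%.12g")


def read_observables(path) -> TrajectoryRecord:
    """Read a CSV written by :func:`write_observables` back into a record."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise ValueError(f"{path}: malformed header line {line!r}")
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing header metadata {missing}")
    for col in ("time_ns", "distance_nm", "kappa2", "efficiency"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return TrajectoryRecord(
        conformer_id=meta["conformer_id"],
        state=meta["state"],
        frame_spacing_ps=float(meta["frame_spacing_ps"]),
        time_ns=df["time_ns"].to_numpy(),
        distance_nm=df["distance_nm"].to_numpy(),
        kappa2=df["kappa2"].to_numpy(),
        efficiency=df["efficiency"].to_numpy(),
    )
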