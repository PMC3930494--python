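"""Configuration files, structure serialization, and run manifests.

The internal format is a JSON document that round-trips a Patch losslessly
(topology, box, phases, link table, full-precision coordinates). PDB and
XYZ are lossy exports for visualization: one residue per saccharide or
stem, one chain per strand.
"""
from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import __version__
from .cg_model import (ConfigurationError, Patch, PatchConfig, Strand,
                       KIND_NAMES, PRESETS, preset)
from .mechanics_engine import ForceFieldParams


class ParseError(ValueError):
    """Malformed structure or configuration file."""


def _plain(obj):
    """Recursively convert numpy scalars/arrays to built-in types."""
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_PROTOCOL_DEFAULTS = {
    "n_relax_steps": 4000,
    "n_equilibration_steps": 4000,
    "n_stress_steps": 2000,
    "strains_per_axis": 6,
    "repeats": 2,
    "h_eff": 4.0,
    "loose_cutoff": 1.6,
    "strict_cutoff": 1.1,
    "min_fraction": 0.01,
}


def load_config(path) -> tuple[PatchConfig, ForceFieldParams, dict]:
    """Read a YAML configuration: patch, force_field, protocol sections.

    An empty file yields all defaults. A ``patch.preset`` key expands one
    of the built-in constructions; other patch keys override its fields.
    Unknown keys raise a descriptive ConfigurationError.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"patch", "force_field", "protocol"}
    if unknown:
        raise ConfigurationError(f"{path}: unknown sections {sorted(unknown)}")

    patch_raw = dict(raw.get("patch") or {})
    preset_name = patch_raw.pop("preset", None)
    base = preset(preset_name) if preset_name else PatchConfig()
    valid = set(PatchConfig.__dataclass_fields__)
    bad = set(patch_raw) - valid
    if bad:
        raise ConfigurationError(f"{path}: unknown patch keys {sorted(bad)}")
    try:
        config = replace(base, **patch_raw)
    except (ConfigurationError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc

    ff_raw = dict(raw.get("force_field") or {})
    valid = set(ForceFieldParams.__dataclass_fields__)
    bad = set(ff_raw) - valid
    if bad:
        raise ConfigurationError(
            f"{path}: unknown force_field keys {sorted(bad)}")
    try:
        params = ForceFieldParams(**ff_raw)
    except ValueError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc

    protocol = dict(_PROTOCOL_DEFAULTS)
    proto_raw = dict(raw.get("protocol") or {})
    bad = set(proto_raw) - set(protocol)
    if bad:
        raise ConfigurationError(
            f"{path}: unknown protocol keys {sorted(bad)}")
    protocol.update(proto_raw)
    return config, params, protocol


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""
    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    version: str = __version__
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    created: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_seed(self, stage: str, seed: int) -> None:
        if stage in self.seeds:
            raise ValueError(f"stage {stage!r} already has a seed recorded")
        self.seeds[stage] = seed

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# internal lossless format
# ---------------------------------------------------------------------------

def write_internal(patch: Patch, path) -> None:
    doc = {
        "format": "pgmech-patch",
        "version": 1,
        "preset_name": patch.preset_name,
        "box": patch.box.tolist(),
        "positions": patch.positions.tolist(),
        "kinds": patch.kinds.tolist(),
        "strand_of_bead": patch.strand_of_bead.tolist(),
        "index_in_strand": patch.index_in_strand.tolist(),
        "strands": [[s.start, s.stop, bool(s.is_periodic)]
                    for s in patch.strands],
        "stem_anchor": patch.stem_anchor.tolist(),
        "stem_phase": patch.stem_phase.tolist(),
        "stem_tip": patch.stem_tip.tolist(),
        "stem_state": patch.stem_state.tolist(),
        "link_donor": patch.link_donor.tolist(),
        "link_acceptor": patch.link_acceptor.tolist(),
        "link_rest": patch.link_rest.tolist(),
        "link_contour": patch.link_contour.tolist(),
        "config": asdict(patch.config) if patch.config is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(_plain(doc), fh)


def read_internal(path) -> Patch:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if doc.get("format") != "pgmech-patch":
        raise ParseError(f"{path}: not a pgmech patch file")
    cfg = PatchConfig(**doc["config"]) if doc.get("config") else None
    patch = Patch(
        box=np.array(doc["box"], dtype=float),
        positions=np.array(doc["positions"], dtype=float),
        kinds=np.array(doc["kinds"], dtype=int),
        strand_of_bead=np.array(doc["strand_of_bead"], dtype=int),
        index_in_strand=np.array(doc["index_in_strand"], dtype=int),
        strands=[Strand(a, b, p) for a, b, p in doc["strands"]],
        stem_anchor=np.array(doc["stem_anchor"], dtype=int),
        stem_phase=np.array(doc["stem_phase"], dtype=float),
        stem_tip=np.array(doc["stem_tip"], dtype=float),
        stem_state=np.array(doc["stem_state"], dtype=int),
        link_donor=np.array(doc["link_donor"], dtype=int),
        link_acceptor=np.array(doc["link_acceptor"], dtype=int),
        link_rest=np.array(doc["link_rest"], dtype=float),
        link_contour=np.array(doc["link_contour"], dtype=float),
        preset_name=doc.get("preset_name", "custom"), config=cfg)
    patch.validate()
    return patch


# ---------------------------------------------------------------------------
# PDB / XYZ exports
# ---------------------------------------------------------------------------

def _patch_atom_array(patch: Patch):
    import biotite.structure as struc
    n = patch.n_beads + patch.n_stems
    arr = struc.AtomArray(n)
    coords = np.vstack([patch.positions, patch.stem_tip]) * 10.0  # nm -> A
    arr.coord = coords.astype(np.float32)
    chain_ids = []
    res_names = []
    res_ids = []
    for i in range(patch.n_beads):
        chain_ids.append(_chain_id(int(patch.strand_of_bead[i])))
        res_names.append("NAG" if KIND_NAMES[int(patch.kinds[i])] == "GlcNAc"
                         else "NAM")
        res_ids.append(int(patch.index_in_strand[i]) + 1)
    for s in range(patch.n_stems):
        anchor = int(patch.stem_anchor[s])
        chain_ids.append(_chain_id(int(patch.strand_of_bead[anchor])))
        res_names.append("PEP")
        res_ids.append(1000 + int(patch.index_in_strand[anchor]) + 1)
    arr.chain_id = np.array(chain_ids, dtype="U4")
    arr.res_name = np.array(res_names, dtype="U5")
    arr.res_id = np.array(res_ids, dtype=int)
    arr.atom_name = np.array(["CA"] * n, dtype="U6")
    arr.element = np.array(["C"] * n, dtype="U2")
    arr.hetero = np.full(n, True)
    return arr


def _chain_id(strand_id: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    return alphabet[strand_id % len(alphabet)]


def write_pdb(patch: Patch, path) -> None:
    """Lossy PDB export: one pseudo-atom per saccharide/stem, chain per strand."""
    import biotite.structure.io.pdb as pdb
    f = pdb.PDBFile()
    f.set_structure(_patch_atom_array(patch))
    f.write(str(path))


def write_xyz(frames, path, comment: str = "pgmech trajectory") -> None:
    """Multi-frame XYZ export (coordinates in nm)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{len(frame)}\n{comment}\n")
            for x, y, z in frame:
                fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> np.ndarray:
    """Read a multi-frame XYZ file written by :func:`write_xyz`."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: bad atom count at line {i + 1}") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: truncated frame at line {i + 1}")
        try:
            frames.append([[float(v) for v in ln.split()[1:4]]
                           for ln in block])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: bad coordinate line near "
                             f"line {i + 3}") from exc
        i += 2 + n
    return np.asarray(frames)


def write_structure(patch_or_frames, path, fmt: str = "internal") -> None:
    """Dispatch on format: 'internal' (lossless), 'pdb', or 'xyz'."""
    if fmt == "internal":
        write_internal(patch_or_frames, path)
    elif fmt == "pdb":
        write_pdb(patch_or_frames, path)
    elif fmt == "xyz":
        frames = patch_or_frames
        if isinstance(frames, Patch):
            frames = np.vstack([frames.positions, frames.stem_tip])
        write_xyz(frames, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_structure(path, fmt: str = "internal"):
    if fmt == "internal":
        return read_internal(path)
    if fmt == "xyz":
        return read_xyz(path)
    raise ValueError(f"unsupported read format {fmt!r}")
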