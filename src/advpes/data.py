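"""Core data containers: configurations, labeled samples, datasets, and their I/O.

A :class:`Configuration` is either a bare d-dimensional vector (toy potential
surfaces) or a molecule given by atomic numbers ``Z`` and Cartesian coordinates
``R`` in Angstrom.  A :class:`LabeledSample` attaches a ground-truth energy and
forces (the negative energy gradient, congruent with the coordinates).  A
:class:`Dataset` is an ordered list of labeled samples with per-sample
provenance tags recording how each point entered the training set.

Vector-kind datasets serialize to JSON; molecular datasets serialize to
extended XYZ with the energy on the comment line and per-atom force columns.
Both round-trip losslessly at double precision.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence

import numpy as np

__all__ = [
    "Configuration",
    "LabeledSample",
    "Dataset",
    "PROVENANCE_TAGS",
    "read_extxyz",
    "write_extxyz",
]

PROVENANCE_TAGS = ("initial", "adversarial", "random", "other")

# Minimal symbol table; anything else round-trips as "E<Z>".
_SYMBOLS = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 18: "Ar", 19: "K", 20: "Ca", 26: "Fe", 35: "Br",
    53: "I",
}
_NUMBERS = {v: k for k, v in _SYMBOLS.items()}


def _symbol(z: int) -> str:
    return _SYMBOLS.get(int(z), f"E{int(z)}")


def _number(sym: str) -> int:
    if sym in _NUMBERS:
        return _NUMBERS[sym]
    m = re.fullmatch(r"E(\d+)", sym)
    if m is None:
        raise ValueError(f"unknown element symbol {sym!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class Configuration:
    """A point in input space: a bare vector or a molecular geometry.

    Parameters
    ----------
    coords : ndarray
        Flat vector of length d (vector kind) or an (n, 3) array in Angstrom
        (molecule kind).
    numbers : ndarray of int, optional
        Atomic numbers; presence marks the configuration as molecule kind.
        Perturbations never touch this field.
    """

    coords: np.ndarray
    numbers: Optional[np.ndarray] = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if self.numbers is not None:
            numbers = np.asarray(self.numbers, dtype=int)
            if numbers.ndim != 1 or numbers.size < 1 or (numbers <= 0).any():
                raise ValueError("atomic numbers must be a 1-d array of positive ints")
            if coords.shape != (numbers.size, 3):
                raise ValueError("molecular coordinates must have shape (n, 3)")
            object.__setattr__(self, "numbers", numbers)
        else:
            coords = coords.ravel()
            if coords.size < 1:
                raise ValueError("empty coordinate vector")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def kind(self) -> str:
        return "vector" if self.numbers is None else "molecule"

    @property
    def dof(self) -> int:
        """Number of scalar degrees of freedom (d, or 3n for molecules)."""
        return self.coords.size

    @property
    def flat(self) -> np.ndarray:
        return self.coords.ravel()

    def with_coords(self, coords: np.ndarray) -> "Configuration":
        """Same composition, new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if self.numbers is not None:
            coords = coords.reshape(self.numbers.size, 3)
        return Configuration(coords, self.numbers)

    def displaced(self, delta: np.ndarray) -> "Configuration":
        """Apply a Cartesian perturbation; atomic numbers are untouched."""
        return self.with_coords(self.coords + np.asarray(delta, float).reshape(self.coords.shape))


@dataclass(frozen=True)
class LabeledSample:
    """A configuration with ground-truth energy and forces."""

    config: Configuration
    energy: float
    forces: np.ndarray

    def __post_init__(self):
        forces = np.asarray(self.forces, dtype=float)
        if forces.shape != self.config.coords.shape:
            raise ValueError("forces shape must equal coordinate shape")
        if not (np.isfinite(self.energy) and np.all(np.isfinite(forces))):
            raise ValueError("energy and forces must be finite")
        object.__setattr__(self, "energy", float(self.energy))
        object.__setattr__(self, "forces", forces)


class Dataset:
    """Ordered collection of labeled samples with provenance tags."""

    def __init__(
        self,
        samples: Iterable[LabeledSample] = (),
        provenance: Optional[Sequence[str]] = None,
    ):
        self.samples: List[LabeledSample] = list(samples)
        if provenance is None:
            provenance = ["initial"] * len(self.samples)
        self.provenance: List[str] = list(provenance)
        if len(self.provenance) != len(self.samples):
            raise ValueError("provenance length must match samples")
        for tag in self.provenance:
            if tag not in PROVENANCE_TAGS:
                raise ValueError(f"unknown provenance tag {tag!r}")
        kinds = {s.config.kind for s in self.samples}
        if len(kinds) > 1:
            raise ValueError("all samples in a dataset must share configuration kind")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[LabeledSample]:
        return iter(self.samples)

    def __getitem__(self, i) -> LabeledSample:
        return self.samples[i]

    @property
    def kind(self) -> str:
        if not self.samples:
            raise ValueError("empty dataset has no kind")
        return self.samples[0].config.kind

    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.samples], dtype=float)

    def coords_matrix(self) -> np.ndarray:
        """(N, dof) matrix of flattened coordinates."""
        return np.array([s.config.flat for s in self.samples], dtype=float)

    def extended(self, samples: Iterable[LabeledSample], tag: str) -> "Dataset":
        """New dataset with ``samples`` appended under provenance ``tag``."""
        new = list(samples)
        return Dataset(self.samples + new, self.provenance + [tag] * len(new))

    def counts_by_provenance(self) -> dict:
        out: dict = {}
        for tag in self.provenance:
            out[tag] = out.get(tag, 0) + 1
        return out

    # ------------------------------------------------------------------ I/O

    def to_json(self, path) -> None:
        if self.samples and self.kind != "vector":
            raise ValueError("JSON serialization is for vector-kind datasets; use extended XYZ")
        records = [
            {
                "coords": s.config.flat.tolist(),
                "energy": s.energy,
                "forces": np.asarray(s.forces).ravel().tolist(),
                "provenance": tag,
            }
            for s, tag in zip(self.samples, self.provenance)
        ]
        with open(path, "w") as fh:
            json.dump(records, fh)

    @classmethod
    def from_json(cls, path) -> "Dataset":
        with open(path) as fh:
            records = json.load(fh)
        samples = [
            LabeledSample(Configuration(np.array(r["coords"])), r["energy"], np.array(r["forces"]))
            for r in records
        ]
        return cls(samples, [r["provenance"] for r in records])

    def to_extxyz(self, path) -> None:
        if self.samples and self.kind != "molecule":
            raise ValueError("extended XYZ is for molecular datasets; use JSON")
        write_extxyz(path, self.samples, self.provenance)

    @classmethod
    def from_extxyz(cls, path) -> "Dataset":
        samples, provenance = read_extxyz(path)
        return cls(samples, provenance)


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

_FMT = "%.17g"  # shortest repr that round-trips IEEE doubles


def write_extxyz(path, samples: Sequence[LabeledSample], provenance: Optional[Sequence[str]] = None) -> None:
    """Write labeled molecular samples as extended XYZ frames.

    Comment line carries ``Properties=species:S:1:pos:R:3:forces:R:3``, the
    frame energy and the provenance tag.
    """
    if provenance is None:
        provenance = ["other"] * len(samples)
    with open(path, "w") as fh:
        for sample, tag in zip(samples, provenance):
            cfg = sample.config
            n = cfg.numbers.size
            fh.write(f"{n}\n")
            fh.write(
                "Properties=species:S:1:pos:R:3:forces:R:3 "
                f"energy={_FMT % sample.energy} provenance={tag}\n"
            )
            F = np.asarray(sample.forces).reshape(n, 3)
            R = cfg.coords
            for i in range(n):
                row = [_symbol(cfg.numbers[i])]
                row += [_FMT % v for v in R[i]]
                row += [_FMT % v for v in F[i]]
                fh.write(" ".join(row) + "\n")


def _parse_comment(line: str) -> dict:
    out = {}
    for key, raw in re.findall(r'(\S+)=(".*?"|\S+)', line):
        out[key] = raw.strip('"')
    return out


def read_extxyz(path):
    """Read extended-XYZ frames written by :func:`write_extxyz`.

    Returns ``(samples, provenance)``.
    """
    samples: List[LabeledSample] = []
    provenance: List[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        fields = _parse_comment(lines[i + 1])
        if "energy" not in fields:
            raise ValueError("extended-XYZ frame missing energy")
        Z = np.empty(n, dtype=int)
        R = np.empty((n, 3))
        F = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            Z[j] = _number(parts[0])
            R[j] = [float(v) for v in parts[1:4]]
            F[j] = [float(v) for v in parts[4:7]]
        samples.append(LabeledSample(Configuration(R, Z), float(fields["energy"]), F))
        provenance.append(fields.get("provenance", "other"))
        i += 2 + n
    return samples, provenance
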