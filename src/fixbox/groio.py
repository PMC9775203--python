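"""Reading and writing fixed-width gro structure files.

The gro dialect is the GROMACS structure format: a title line, an atom
count, ``N`` fixed-column atom lines
(``%5d%-5s%5s%5d%8.3f%8.3f%8.3f`` plus optional ``%8.4f`` velocities)
and a final free-format box line.  A file may hold several snapshots by
simple concatenation; this module reads and writes them all.

Coordinates are in nm with three decimals on disk; in memory they are
kept in double precision and only rounded on write.  The box line with
three fields describes a rectangular box; with nine fields it carries a
general triclinic cell in the order
``v1x v2y v3z v1y v1z v2x v2z v3x v3y``.

This reader/writer is deliberately self-contained: the pipeline needs
multi-snapshot streams, byte-stable round trips and per-snapshot boxes,
which is a narrower and stricter contract than general-purpose structure
readers provide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

from .errors import GroParseError, GroWriteError
from .triclinic import TriclinicBox, make_box

# gro serial fields are five columns wide; numbers wrap modulo 100000
SERIAL_MODULUS = 100000


@dataclass
class AtomRecord:
    """One atom line of a gro file (positions in nm, velocities in nm/ps)."""

    residue_number: int
    residue_name: str
    atom_name: str
    atom_number: int
    position: tuple[float, float, float]
    velocity: tuple[float, float, float] | None = None


@dataclass
class Configuration:
    """One snapshot: title, ordered atom records and the periodic box."""

    title: str
    atoms: list[AtomRecord]
    box: TriclinicBox

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """``(N, 3)`` array of positions in nm (a fresh copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(self, positions: np.ndarray) -> "Configuration":
        """A copy of this snapshot with new coordinates (box unchanged)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ValueError(
                f"expected positions of shape ({self.n_atoms}, 3), "
                f"got {positions.shape}"
            )
        atoms = [
            replace(a, position=tuple(float(x) for x in p))
            for a, p in zip(self.atoms, positions)
        ]
        return Configuration(title=self.title, atoms=atoms, box=self.box)


def _parse_float(text: str, what: str, line_number: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise GroParseError(f"unparsable {what}: {text.strip()!r}", line_number)


def _parse_box_line(line: str, line_number: int,
                    center_convention: str) -> TriclinicBox:
    fields = line.split()
    try:
        values = [float(f) for f in fields]
    except ValueError:
        raise GroParseError(f"unparsable box line: {line.strip()!r}", line_number)
    if len(values) == 3:
        v1x, v2y, v3z = values
        b1, b2, b3 = (v1x, 0.0, 0.0), (0.0, v2y, 0.0), (0.0, 0.0, v3z)
    elif len(values) == 9:
        v1x, v2y, v3z, v1y, v1z, v2x, v2z, v3x, v3y = values
        b1 = (v1x, v1y, v1z)
        b2 = (v2x, v2y, v2z)
        b3 = (v3x, v3y, v3z)
    else:
        raise GroParseError(
            f"box line must have 3 or 9 fields, found {len(values)}",
            line_number,
        )
    return make_box(b1, b2, b3, center_convention=center_convention)


def _parse_atom_line(line: str, line_number: int) -> AtomRecord:
    body = line.rstrip("\n")
    if len(body) < 44:
        raise GroParseError(
            f"atom line too short ({len(body)} < 44 columns)", line_number
        )
    try:
        residue_number = int(body[0:5])
        atom_number = int(body[15:20])
    except ValueError:
        raise GroParseError(
            f"unparsable serial fields in atom line: {body[:20]!r}", line_number
        )
    position = (
        _parse_float(body[20:28], "x coordinate", line_number),
        _parse_float(body[28:36], "y coordinate", line_number),
        _parse_float(body[36:44], "z coordinate", line_number),
    )
    velocity = None
    if len(body) >= 68:  # three more 8.4f fields: velocities present
        velocity = (
            _parse_float(body[44:52], "x velocity", line_number),
            _parse_float(body[52:60], "y velocity", line_number),
            _parse_float(body[60:68], "z velocity", line_number),
        )
    return AtomRecord(
        residue_number=residue_number,
        residue_name=body[5:10].strip(),
        atom_name=body[10:15].strip(),
        atom_number=atom_number,
        position=position,
        velocity=velocity,
    )


def read_configurations(stream: TextIO | Iterable[str],
                        center_convention: str = "half-sum",
                        ) -> Iterator[Configuration]:
    """Yield every snapshot of a (possibly multi-snapshot) gro stream.

    ``center_convention`` selects where the geometric center ``g`` of the
    parsed boxes sits; gro files lay the box with one corner at the
    origin, for which ``half-sum`` is the natural choice.
    """
    lines = iter(stream)
    line_number = 0

    def next_line() -> str | None:
        nonlocal line_number
        try:
            line = next(lines)
        except StopIteration:
            return None
        line_number += 1
        return line

    while True:
        title = next_line()
        if title is None:
            return
        if title.strip() == "" and next((c for c in title if c != "\n"), None) is None:
            # tolerate trailing blank lines at end of file
            remainder = [ln for ln in lines if ln.strip()]
            if remainder:
                raise GroParseError("unexpected blank title line", line_number)
            return
        count_line = next_line()
        if count_line is None:
            raise GroParseError("missing atom-count line", line_number)
        try:
            n_atoms = int(count_line.strip())
        except ValueError:
            raise GroParseError(
                f"malformed atom-count line: {count_line.strip()!r}", line_number
            )
        atoms = []
        for _ in range(n_atoms):
            atom_line = next_line()
            if atom_line is None:
                raise GroParseError(
                    f"file ends after {len(atoms)} of {n_atoms} atom lines",
                    line_number,
                )
            atoms.append(_parse_atom_line(atom_line, line_number))
        box_line = next_line()
        if box_line is None:
            raise GroParseError("missing box line", line_number)
        box = _parse_box_line(box_line, line_number, center_convention)
        yield Configuration(title=title.rstrip("\n"), atoms=atoms, box=box)


def _format_atom_line(atom: AtomRecord) -> str:
    x, y, z = atom.position
    line = "%5d%-5s%5s%5d%8.3f%8.3f%8.3f" % (
        atom.residue_number % SERIAL_MODULUS,
        atom.residue_name[:5],
        atom.atom_name[:5],
        atom.atom_number % SERIAL_MODULUS,
        x, y, z,
    )
    if atom.velocity is not None:
        line += "%8.4f%8.4f%8.4f" % atom.velocity
    return line


def _format_box_line(box: TriclinicBox) -> str:
    B = box.B
    off_diagonal = (B[1, 0], B[2, 0], B[0, 1], B[2, 1], B[0, 2], B[1, 2])
    if all(abs(v) < 5e-6 for v in off_diagonal):  # below the printed precision
        return "%10.5f%10.5f%10.5f" % (B[0, 0], B[1, 1], B[2, 2])
    # gro nine-component order: v1x v2y v3z v1y v1z v2x v2z v3x v3y
    return ("%10.5f" * 9) % (
        B[0, 0], B[1, 1], B[2, 2],
        B[1, 0], B[2, 0],
        B[0, 1], B[2, 1],
        B[0, 2], B[1, 2],
    )


def write_configurations(configs: Iterable[Configuration],
                         stream: TextIO) -> None:
    """Write snapshots in gro layout, preserving each snapshot's own box.

    Atom and residue serials are written modulo 100000 (the gro field
    width), so overflowing numbers wrap rather than breaking the layout.
    """
    wrote_any = False
    for config in configs:
        if config.n_atoms == 0:
            raise GroWriteError("cannot write a configuration with no atoms")
        stream.write(config.title.rstrip("\n") + "\n")
        stream.write("%5d\n" % config.n_atoms)
        for atom in config.atoms:
            stream.write(_format_atom_line(atom) + "\n")
        stream.write(_format_box_line(config.box) + "\n")
        wrote_any = True
    if not wrote_any:
        raise GroWriteError("no configurations to write")


def read_file(path, center_convention: str = "half-sum") -> list[Configuration]:
    with open(path) as handle:
        return list(read_configurations(handle, center_convention))


def write_file(path, configs: Sequence[Configuration]) -> None:
    with open(path, "w") as handle:
        write_configurations(configs, handle)
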