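"""Coloring scripts that paint HDX results onto protein structures.

Emits command/attribute files for external molecular-graphics programs
(PyMOL ``.pml`` command files; classic Chimera ``defattr`` attribute files
plus a command file) rather than touching the PDB itself.  Output is a
pure function of the color map, so files are byte-stable and golden-file
testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hdxdiff.summaries import ResidueTrack

#: class -> RGB (0-255); red/blue/gray convention for deprotected/protected
DEFAULT_PALETTE = {
    "deprotected": (215, 25, 28),
    "protected": (44, 123, 182),
    "mixed": (123, 50, 148),
    "none": (224, 224, 224),
    "non-significant": (154, 154, 154),
    "covered": (44, 123, 182),
    "no_data": (224, 224, 224),
}

#: gradient endpoints for scalar tracks (low, high)
DEFAULT_GRADIENT = ((235, 235, 235), (8, 48, 107))


class StructureExportError(ValueError):
    pass


@dataclass
class ResidueColorMap:
    """Residue -> class (or scalar) assignment on one structure chain."""
    chain: str
    entries: list[tuple[int, object]]          # (residue number, class|value)
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    gradient: tuple = DEFAULT_GRADIENT
    offset: int = 0
    scalar: bool = False

    def __post_init__(self):
        resis = [r for r, _ in self.entries]
        if len(resis) != len(set(resis)):
            raise StructureExportError("duplicate residue numbers in color map")
        for rgb in self.palette.values():
            if any(not 0 <= c <= 255 for c in rgb):
                raise StructureExportError("RGB components must be in [0, 255]")


def build_color_map(track, chain: str = "A", offset: int = 0,
                    palette: dict | None = None,
                    no_data_class: str = "no_data") -> ResidueColorMap:
    """Build a color map from a residue track or a barcode column.

    Parameters
    ----------
    track : ResidueTrack, mapping, or pandas Series
        A :class:`~hdxdiff.summaries.ResidueTrack` (covered/uncovered or
        scalar redundancy), or a residue -> class mapping such as one
        column of the barcode matrix.
    chain : str
        Structure chain identifier.
    offset : int
        Added to every residue number to translate construct numbering to
        structure numbering.
    """
    palette = dict(DEFAULT_PALETTE if palette is None else palette)
    entries: list[tuple[int, object]] = []
    scalar = False
    if isinstance(track, ResidueTrack):
        scalar = bool(track.redundancy.max() > 1)
        for resi in range(1, track.protein_length + 1):
            if track.coverage[resi - 1]:
                value = int(track.redundancy[resi - 1]) if scalar else "covered"
            else:
                value = 0 if scalar else no_data_class
            entries.append((resi + offset, value))
    else:
        items = track.items() if hasattr(track, "items") else track
        for resi, value in items:
            entries.append((int(resi) + offset, value))
        scalar = any(isinstance(v, (int, float, np.integer, np.floating))
                     for _, v in entries)
    return ResidueColorMap(chain=chain, entries=sorted(entries),
                           palette=palette, offset=offset, scalar=scalar)


def _runs(resis: list[int]) -> list[tuple[int, int]]:
    """Compress a sorted residue list into contiguous (lo, hi) runs."""
    runs = []
    for r in resis:
        if runs and r == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], r)
        else:
            runs.append((r, r))
    return runs


def _interp_color(value: float, lo: float, hi: float,
                  gradient) -> tuple[int, int, int]:
    t = 0.0 if hi <= lo else (value - lo) / (hi - lo)
    return tuple(int(round(a + t * (b - a)))
                 for a, b in zip(gradient[0], gradient[1]))


def write_pymol_script(color_map: ResidueColorMap, path,
                       suppress_no_data: bool = False) -> None:
    """Write a PyMOL command file applying the color map.

    Class maps define one named color per class and color contiguous
    residue runs with ``resi lo-hi`` selections; scalar maps bin values
    onto the gradient.  With ``suppress_no_data`` the no-data/none lines
    are omitted.
    """
    if not color_map.entries:
        raise StructureExportError("empty color map")
    lines = ["# hdxdiff structure coloring (PyMOL)",
             f"# chain {color_map.chain}, numbering offset {color_map.offset:+d}"]
    if color_map.scalar:
        values = [float(v) for _, v in color_map.entries]
        lo, hi = min(values), max(values)
        by_color: dict[tuple, list[int]] = {}
        for resi, v in color_map.entries:
            by_color.setdefault(
                _interp_color(float(v), lo, hi, color_map.gradient),
                []).append(resi)
        for i, (rgb, resis) in enumerate(sorted(by_color.items())):
            name = f"hdx_scalar_{i:03d}"
            lines.append(f"set_color {name}, "
                         f"[{rgb[0] / 255:.4f}, {rgb[1] / 255:.4f}, {rgb[2] / 255:.4f}]")
            for lo_r, hi_r in _runs(sorted(resis)):
                sel = f"resi {lo_r}" if lo_r == hi_r else f"resi {lo_r}-{hi_r}"
                lines.append(f"color {name}, chain {color_map.chain} and {sel}")
    else:
        by_class: dict[str, list[int]] = {}
        for resi, cls in color_map.entries:
            by_class.setdefault(str(cls), []).append(resi)
        for cls in sorted(by_class):
            if suppress_no_data and cls in ("no_data", "none"):
                continue
            rgb = color_map.palette.get(cls, color_map.palette["no_data"])
            name = f"hdx_{cls}"
            lines.append(f"set_color {name}, "
                         f"[{rgb[0] / 255:.4f}, {rgb[1] / 255:.4f}, {rgb[2] / 255:.4f}]")
            for lo_r, hi_r in _runs(sorted(by_class[cls])):
                sel = f"resi {lo_r}" if lo_r == hi_r else f"resi {lo_r}-{hi_r}"
                lines.append(f"color {name}, chain {color_map.chain} and {sel}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_chimera_script(color_map: ResidueColorMap, attr_path,
                         com_path=None, attribute: str = "hdx") -> None:
    """Write a classic-Chimera ``defattr`` attribute file and a command
    file applying a color mapping.

    Scalar maps get numeric attribute values rendered with ``rangecolor``;
    class maps get one ``color`` command per class selection.
    """
    if not color_map.entries:
        raise StructureExportError("empty color map")
    attr_lines = [f"# hdxdiff attribute file (chain {color_map.chain})",
                  f"attribute: {attribute}",
                  "match mode: 1-to-1",
                  "recipient: residues"]
    for resi, value in color_map.entries:
        val = f"{float(value):g}" if color_map.scalar else str(value)
        attr_lines.append(f"\t:{resi}.{color_map.chain}\t{val}")
    with open(attr_path, "w", newline="\n") as fh:
        fh.write("\n".join(attr_lines) + "\n")

    if com_path is None:
        return
    # reference the attribute file by a fixed name so the command file is a
    # pure function of the color map; users adjust the path if they rename it
    com_lines = ["# hdxdiff coloring commands (Chimera)",
                 f"defattr {attribute}.defattr"]
    if color_map.scalar:
        values = [float(v) for _, v in color_map.entries]
        lo, hi = min(values), max(values)
        lo_rgb, hi_rgb = color_map.gradient
        com_lines.append(
            f"rangecolor {attribute} {lo:g} "
            f"{lo_rgb[0] / 255:.4f},{lo_rgb[1] / 255:.4f},{lo_rgb[2] / 255:.4f} "
            f"{hi:g} "
            f"{hi_rgb[0] / 255:.4f},{hi_rgb[1] / 255:.4f},{hi_rgb[2] / 255:.4f}")
    else:
        by_class: dict[str, list[int]] = {}
        for resi, cls in color_map.entries:
            by_class.setdefault(str(cls), []).append(resi)
        for cls in sorted(by_class):
            rgb = color_map.palette.get(cls, color_map.palette["no_data"])
            sel = ",".join(f"{lo}-{hi}" if lo != hi else f"{lo}"
                           for lo, hi in _runs(sorted(by_class[cls])))
            com_lines.append(
                f"color {rgb[0] / 255:.4f},{rgb[1] / 255:.4f},{rgb[2] / 255:.4f} "
                f":{sel}.{color_map.chain}")
    with open(com_path, "w", newline="\n") as fh:
        fh.write("\n".join(com_lines) + "\n")


def parse_chimera_attributes(path) -> dict[int, str]:
    """Parse a defattr file back to residue -> value (test/verification aid)."""
    out: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("\t"):
                continue
            sel, value = line.strip().split("\t")
            resi = int(sel.lstrip(":").split(".")[0])
            out[resi] = value
    return out
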