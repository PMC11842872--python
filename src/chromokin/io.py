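"""Plain-text I/O: track tables, scheme configs, outlines, BED, matrices."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cbd import NuclearOutline
from .contacts import ContactMap
from .schemes import IlluminationScheme, Track, build_scheme, dataframe_to_tracks, tracks_to_dataframe

__all__ = [
    "read_tracks_tsv",
    "write_tracks_tsv",
    "read_scheme_yaml",
    "write_scheme_yaml",
    "read_outlines",
    "write_outlines",
    "read_bed",
    "beads_from_bed",
    "read_contact_map",
    "write_contact_map",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


def write_tracks_tsv(tracks: Sequence[Track] | pd.DataFrame, path: str | Path) -> None:
    df = tracks if isinstance(tracks, pd.DataFrame) else tracks_to_dataframe(tracks)
    df.to_csv(path, sep="\t", index=False)


def read_tracks_tsv(path: str | Path, as_tracks: bool = True) -> list[Track] | pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    return dataframe_to_tracks(df) if as_tracks else df


def write_scheme_yaml(scheme: IlluminationScheme, path: str | Path) -> None:
    doc = {
        "name": scheme.name,
        "repeats": scheme.repeats,
        "events": [
            {"exposure_s": ev.exposure, "readout_s": ev.readout, "dark_s": ev.dark}
            for ev in scheme.cycle
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scheme_yaml(path: str | Path) -> IlluminationScheme:
    doc = yaml.safe_load(Path(path).read_text())
    events = [
        (float(ev["exposure_s"]), float(ev.get("readout_s", 0.0)), float(ev.get("dark_s", 0.0)))
        for ev in doc["events"]
    ]
    return build_scheme(doc["name"], events, repeats=int(doc.get("repeats", 1)))


def write_outlines(outline: NuclearOutline, path: str | Path) -> None:
    """Per-movie keyframe vertex lists as structured text."""
    lines = []
    for frame, verts in outline.keyframes:
        lines.append(f"frame {frame}")
        lines.extend(f"{x:.6f}\t{y:.6f}" for x, y in verts)
    Path(path).write_text("\n".join(lines) + "\n")


def read_outlines(path: str | Path) -> NuclearOutline:
    keyframes: list[tuple[int, list[list[float]]]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("frame"):
            keyframes.append((int(line.split()[1]), []))
        else:
            x, y = line.split()
            keyframes[-1][1].append([float(x), float(y)])
    return NuclearOutline([(f, np.asarray(v)) for f, v in keyframes])


def read_bed(path: str | Path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end and optional name/score/strand.

    Coordinates are 0-based half-open; track/browser/comment lines skipped.
    """
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        row = {
            "chrom": fields[0],
            "start": int(fields[1]),
            "end": int(fields[2]),
            "name": fields[3] if len(fields) > 3 else ".",
            "score": fields[4] if len(fields) > 4 else ".",
            "strand": fields[5] if len(fields) > 5 else ".",
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def beads_from_bed(bed: pd.DataFrame, resolution_kb: float, mode: str = "center") -> np.ndarray:
    """Map BED intervals to bead indices at a lattice resolution.

    ``center`` uses the interval midpoint, ``start`` the 0-based start.
    """
    res_bp = int(round(resolution_kb * 1000))
    if mode == "center":
        pos = (bed["start"].to_numpy() + bed["end"].to_numpy()) // 2
    elif mode == "start":
        pos = bed["start"].to_numpy()
    else:
        raise ValueError("mode must be 'center' or 'start'")
    return (pos // res_bp).astype(int)


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    header = f"resolution_kb={cmap.resolution_kb} normalization={cmap.normalization}"
    np.savetxt(path, cmap.matrix, header=header)


def read_contact_map(path: str | Path) -> ContactMap:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(item.split("=") for item in header.split())
    matrix = np.loadtxt(path)
    return ContactMap(
        matrix,
        resolution_kb=float(meta.get("resolution_kb", 1.0)),
        normalization=meta.get("normalization", "raw"),
    )
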