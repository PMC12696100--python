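"""Readers and writers for the package's table and image formats.

Every CSV carries a versioned dialect header comment as its first line::

    # forkstat-csv v1 kind=localizations units=nm

Readers reject unknown versions or kinds instead of guessing.  SMLM tables
are always nm; fiber tables are always um; the units are stated in the
header.  Movies, masks and renders are multi-page TIFF.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .linking import BlinkEvent
from .localize import Localization
from .simulate import Movie

__all__ = [
    "DIALECT_VERSION",
    "RunManifest",
    "write_table",
    "read_table",
    "localizations_to_frame",
    "frame_to_localizations",
    "events_to_frame",
    "frame_to_events",
    "write_movie",
    "read_movie",
    "file_sha256",
]

DIALECT_VERSION = "v1"

_KIND_UNITS = {
    "localizations": "nm",
    "events": "nm",
    "points": "nm",
    "truth": "nm",
    "fibers": "um",
    "fiber-gaps": "um",
    "dose": "uM",
    "paircorr": "nm",
    "foci": "nm",
    "nuclei": "um",
}


def _header(kind: str) -> str:
    return f"# forkstat-csv {DIALECT_VERSION} kind={kind} units={_KIND_UNITS[kind]}"


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write a tidy table in the versioned CSV dialect."""
    if kind not in _KIND_UNITS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(kind) + "\n")
        # %.17g guarantees lossless float64 round-trips through the reader
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    """Read a dialect CSV, validating version (and kind when given)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        parts = first.split()
        if len(parts) < 3 or parts[0] != "#" or parts[1] != "forkstat-csv":
            raise ValueError(f"{path}: not a forkstat CSV (missing dialect header)")
        if parts[2] != DIALECT_VERSION:
            raise ValueError(f"{path}: unsupported dialect version {parts[2]!r}")
        meta = dict(p.split("=", 1) for p in parts[3:] if "=" in p)
        if kind is not None and meta.get("kind") != kind:
            raise ValueError(f"{path}: expected kind={kind}, found {meta.get('kind')}")
        return pd.read_csv(fh, float_precision="round_trip")


_LOC_COLS = ["frame", "x_nm", "y_nm", "photons", "background", "sigma_nm",
             "crlb_x_nm", "crlb_y_nm", "loglik", "channel"]


def localizations_to_frame(locs: list[Localization]) -> pd.DataFrame:
    return pd.DataFrame(
        [(L.frame, L.x_nm, L.y_nm, L.photons, L.background, L.psf_sigma_nm,
          L.crlb_x_nm, L.crlb_y_nm, L.loglik, L.channel) for L in locs],
        columns=_LOC_COLS)


def frame_to_localizations(df: pd.DataFrame) -> list[Localization]:
    return [Localization(x_nm=r.x_nm, y_nm=r.y_nm, frame=int(r.frame),
                         photons=r.photons, background=r.background,
                         psf_sigma_nm=r.sigma_nm, crlb_x_nm=r.crlb_x_nm,
                         crlb_y_nm=r.crlb_y_nm, channel=str(r.channel),
                         loglik=r.loglik)
            for r in df.itertuples(index=False)]


_EVENT_COLS = ["x_nm", "y_nm", "first_frame", "last_frame", "n_locs",
               "total_photons", "channel"]


def events_to_frame(events: list[BlinkEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.x_nm, e.y_nm, e.first_frame, e.last_frame, e.n_locs,
          e.total_photons, e.channel) for e in events],
        columns=_EVENT_COLS)


def frame_to_events(df: pd.DataFrame) -> list[BlinkEvent]:
    return [BlinkEvent(x_nm=r.x_nm, y_nm=r.y_nm, first_frame=int(r.first_frame),
                       last_frame=int(r.last_frame), n_locs=int(r.n_locs),
                       total_photons=r.total_photons, channel=str(r.channel))
            for r in df.itertuples(index=False)]


def write_movie(path, movie: Movie) -> None:
    """Write a movie as a multi-page float32 TIFF; pixel size and channel go
    in the image description."""
    desc = json.dumps({"pixel_size_nm": movie.pixel_size_nm,
                       "channel": movie.channel})
    tifffile.imwrite(path, movie.frames.astype(np.float32), description=desc,
                     photometric="minisblack")


def read_movie(path) -> Movie:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(frames=frames,
                 pixel_size_nm=float(meta.get("pixel_size_nm", 65.0)),
                 channel=str(meta.get("channel", "ch0")))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted by every CLI run: configuration
    snapshot, input hashes, seed, software version and QC counters.

    ``seed_used`` is False for stages with no randomness, which ignore the
    seed and say so here.
    """

    subcommand: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: dict = field(default_factory=dict)  # path -> sha256
    seed: int | None = None
    seed_used: bool = True
    qc: dict = field(default_factory=dict)
    version: str = ""
    python: str = field(default_factory=platform.python_version)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_sha256(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
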