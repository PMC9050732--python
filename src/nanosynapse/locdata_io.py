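"""Localization-table input/output and acquisition frame-window filtering.

A localization table holds one record per detected single-molecule emission
event: 3D position in nanometres, the camera frame the event was detected in,
and the channel (target protein) it belongs to.  Tables are exchanged as
UTF-8 delimited text with a mandatory header::

    x_nm,y_nm,z_nm,frame,channel[,photons]

Coordinates use '.' as the decimal separator; a tab delimiter is accepted via
an explicit flag.  Early acquisition frames are routinely discarded in dSTORM
because the initial emitter density is too high for reliable localization;
:func:`filter_frames` implements that per-channel exclusion window.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import FormatError, RowParseError, UnknownChannelError

REQUIRED_COLUMNS = ("x_nm", "y_nm", "z_nm", "frame", "channel")
OPTIONAL_COLUMNS = ("photons",)

#: Per-channel acquisition windows: (total frames, excluded prefix).
#: Tenm3 is imaged longest and loses the most early frames; the synaptic
#: marker channels use shorter windows.
FRAME_WINDOW_PRESETS = {
    "Tenm3": (10_000, 3_000),
    "Bassoon": (7_000, 2_000),
    "Homer1": (7_000, 1_000),
}


@dataclass(frozen=True)
class FrameWindow:
    """Valid acquisition window for one channel.

    Frames are 0-based; records with ``frame < excluded_prefix`` or
    ``frame >= total_frames`` are discarded (half-open window
    ``[excluded_prefix, total_frames)`` retained).
    """

    channel: str
    total_frames: int
    excluded_prefix: int = 0

    def __post_init__(self):
        if self.total_frames <= 0:
            raise ValueError("total_frames must be positive")
        if not (0 <= self.excluded_prefix < self.total_frames):
            raise ValueError("excluded_prefix must satisfy 0 <= excluded_prefix < total_frames")

    @classmethod
    def preset(cls, channel: str) -> "FrameWindow":
        try:
            total, excl = FRAME_WINDOW_PRESETS[channel]
        except KeyError:
            raise UnknownChannelError(f"no frame-window preset for channel {channel!r}")
        return cls(channel, total, excl)


@dataclass
class LocalizationTable:
    """In-memory localization table backed by a pandas DataFrame.

    The DataFrame index identifies records stably across filtering steps
    (frame exclusion, density denoising), which is what lets downstream
    cluster memberships be compared against ground truth.
    """

    df: pd.DataFrame
    field_extent: tuple | None = None  # (x_min, x_max, y_min, y_max, z_min, z_max) nm
    provenance: str = ""
    #: channel labels the table declares; defaults to the labels present in
    #: the data.  Filtering can legitimately empty a channel without
    #: un-declaring it (which keeps frame filtering idempotent).
    declared_channels: frozenset | None = None

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        if self.field_extent is not None and len(self.df):
            x0, x1, y0, y1, z0, z1 = self.field_extent
            xyz = self.df[["x_nm", "y_nm", "z_nm"]].to_numpy()
            lo = np.array([x0, y0, z0])
            hi = np.array([x1, y1, z1])
            if (xyz < lo).any() or (xyz > hi).any():
                raise FormatError("localization outside declared field_extent")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def channels(self) -> set:
        if self.declared_channels is not None:
            return set(self.declared_channels)
        return set(self.df["channel"].unique())

    def coords(self, channel: str | None = None) -> np.ndarray:
        """(n, 3) array of x, y, z in nm, optionally restricted to a channel."""
        df = self.df if channel is None else self.channel_df(channel)
        return df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)

    def channel_df(self, channel: str) -> pd.DataFrame:
        if channel not in self.channels:
            raise UnknownChannelError(f"channel {channel!r} not in table (has {sorted(self.channels)})")
        return self.df[self.df["channel"] == channel]

    def drop(self, index) -> "LocalizationTable":
        """Copy of the table with the given index labels removed."""
        return replace(self, df=self.df.drop(index=index))


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_nm": pd.Series(dtype=float),
            "y_nm": pd.Series(dtype=float),
            "z_nm": pd.Series(dtype=float),
            "frame": pd.Series(dtype=int),
            "channel": pd.Series(dtype=object),
        }
    )


def read_localizations(path, delimiter: str = ",") -> LocalizationTable:
    """Read a localization table; raise on any malformed row.

    Unparseable rows are reported (with the 1-based file line number), never
    silently dropped — a corrupted export should fail loudly, not bias the
    downstream cluster statistics.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return LocalizationTable(_empty_frame(), provenance=str(path))

    out = pd.DataFrame(index=df.index)
    for col in ("x_nm", "y_nm", "z_nm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & ~df[col].isna()
        bad |= df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise RowParseError(line, f"non-numeric value {df[col].iloc[bad.idxmax()]!r} in column {col}")
        if not np.isfinite(vals.to_numpy()).all():
            line = int(np.flatnonzero(~np.isfinite(vals.to_numpy()))[0]) + 2
            raise RowParseError(line, f"non-finite coordinate in column {col}")
        # re-parse through the correctly-rounded converter so write/read
        # round trips are bit-exact (pandas' fast parser is approximate)
        out[col] = np.array([float(v) for v in df[col]], dtype=float)
    frames = pd.to_numeric(df["frame"], errors="coerce")
    bad = frames.isna() | (frames < 0) | (frames != frames.round())
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise RowParseError(line, f"frame must be a non-negative integer, got {df['frame'].iloc[bad.idxmax()]!r}")
    out["frame"] = frames.astype(int)
    out["channel"] = df["channel"].astype(str)
    if "photons" in df.columns:
        photons = pd.to_numeric(df["photons"], errors="coerce")
        out["photons"] = photons.astype(float)
    return LocalizationTable(out, provenance=str(path))


def write_localizations(table: LocalizationTable, path, delimiter: str = ",") -> None:
    """Write the table in the package dialect (full float precision, so a
    write-then-read round trip reproduces coordinates exactly)."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in table.df.columns]
    # %.17g guarantees binary-exact float round trips through text
    table.df.to_csv(path, sep=delimiter, columns=cols, index=False, float_format="%.17g")


def read_localizations_str(text: str, delimiter: str = ",") -> LocalizationTable:
    """Convenience wrapper for parsing an in-memory table string."""
    return read_localizations(io.StringIO(text), delimiter=delimiter)


def filter_frames(table: LocalizationTable, window: FrameWindow) -> LocalizationTable:
    """Remove out-of-window localizations of ``window.channel``.

    Records of the window's channel with ``frame < excluded_prefix`` or
    ``frame >= total_frames`` are dropped; every other channel passes through
    untouched.  Idempotent, and conserves per-channel counts
    (retained + removed = input).
    """
    if window.channel not in table.channels:
        raise UnknownChannelError(
            f"channel {window.channel!r} not in table (has {sorted(table.channels)})"
        )
    df = table.df
    in_channel = df["channel"] == window.channel
    keep = ~in_channel | ((df["frame"] >= window.excluded_prefix) & (df["frame"] < window.total_frames))
    return replace(table, df=df[keep], declared_channels=frozenset(table.channels))
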