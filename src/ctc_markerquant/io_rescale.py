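"""Loading and intensity restoration of archived fluorescence thumbnails.

CellSearch-style analyzers acquire four fluorescent channels (DAPI nuclear
stain, cytokeratin-PE, CD45-APC and a free marker channel, here HER-2-FITC)
with a 12-bit camera (intensities 0..4095) but archive each thumbnail as an
8-bit image whose brightness is stretched to the brightest pixel of the
channel.  The original per-channel minimum and maximum are recorded in the
TIFF header, so the true 12-bit intensities can be restored by the inverse
affine map.  This module reads such thumbnails, restores them, and parses the
small CSV score tables used by the scoring stage.

Header convention: the archive dialect is proprietary, so fixtures written by
this package store the original range as ``min=<int>;max=<int>`` key-value
pairs in the per-page ``ImageDescription`` tag.  ``load_thumbnail`` accepts a
``header_parser`` callable so other dialects can be plugged in.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import tifffile

from .errors import ConfigurationError, FormatError, ParseError, StateError

logger = logging.getLogger(__name__)

#: Canonical channel names, in the conventional display order.
CHANNELS: tuple[str, ...] = ("DAPI", "CK", "CD45", "MARKER1")

#: Full scale of the 12-bit camera: the maximal possible intensity.
FULL_SCALE_12BIT: int = 4095

#: Default pixel pitch in micrometres (a 6.4 um size bar spans 10 px).
DEFAULT_PIXEL_SIZE_UM: float = 0.64

#: Valid ordinal immunohistochemistry-style score tokens and their ranks.
ORDINAL_TOKENS: dict[str, int] = {"0": 0, "1+": 1, "2+": 2, "3+": 3}
BINARY_TOKENS: frozenset[str] = frozenset({"positive", "negative"})


@dataclass(frozen=True)
class FluorescentFrame:
    """One channel's pixel grid plus the metadata needed to restore it.

    Parameters
    ----------
    channel_name:
        One of :data:`CHANNELS`.
    pixels:
        2-D array of non-negative intensities (float once rescaled).
    stored_bit_depth:
        8 for archived frames, 12 for native acquisitions.
    header_min, header_max:
        Original channel range recorded at archive time; bounded by the
        12-bit full scale.
    pixel_size_um:
        Physical pixel pitch in micrometres.
    is_rescaled:
        True once pixel values are on the restored 12-bit scale.
    """

    channel_name: str
    pixels: np.ndarray
    stored_bit_depth: int = 8
    header_min: float = 0.0
    header_max: float = float(FULL_SCALE_12BIT)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    is_rescaled: bool = False

    def __post_init__(self) -> None:
        if self.channel_name not in CHANNELS:
            raise ConfigurationError(
                f"unknown channel {self.channel_name!r}; expected one of {CHANNELS}"
            )
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise FormatError("pixel grid must be a non-empty 2-D array")
        object.__setattr__(self, "pixels", px)
        if not (0 <= self.header_min <= self.header_max <= FULL_SCALE_12BIT):
            raise FormatError(
                f"header range ({self.header_min}, {self.header_max}) must satisfy "
                f"0 <= min <= max <= {FULL_SCALE_12BIT}"
            )
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        if self.is_rescaled:
            lo, hi = float(px.min()), float(px.max())
            if lo < self.header_min - 1e-9 or hi > self.header_max + 1e-9:
                raise FormatError(
                    "rescaled pixels must lie within the header range: "
                    f"data [{lo}, {hi}] vs header [{self.header_min}, {self.header_max}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class EventThumbnail:
    """A per-event bundle of the four aligned channel frames."""

    event_id: str
    sample_id: str
    patient_id: str
    frames: Mapping[str, FluorescentFrame]
    manual_her2_score: int | None = None  # ordinal rank 0..3 or None

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.frames)
        if missing:
            raise ConfigurationError(f"thumbnail missing channels: {sorted(missing)}")
        shapes = {f.shape for f in self.frames.values()}
        sizes = {f.pixel_size_um for f in self.frames.values()}
        if len(shapes) != 1 or len(sizes) != 1:
            raise FormatError("all four frames must share shape and pixel size")
        if self.manual_her2_score is not None and self.manual_her2_score not in (0, 1, 2, 3):
            raise FormatError("manual_her2_score must be an ordinal rank in 0..3")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.frames.values())).shape


_MINMAX_RE = re.compile(r"min=(\d+)\s*;\s*max=(\d+)")


def parse_minmax_description(description: str | None) -> tuple[float, float] | None:
    """Default header parser: ``min=<int>;max=<int>`` in ImageDescription."""
    if not description:
        return None
    m = _MINMAX_RE.search(description)
    if m is None:
        return None
    return float(m.group(1)), float(m.group(2))


HeaderParser = Callable[[str | None], "tuple[float, float] | None"]


def load_thumbnail(
    path: str | Path,
    channel_map: Mapping[int, str],
    *,
    event_id: str | None = None,
    sample_id: str = "",
    patient_id: str = "",
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    header_parser: HeaderParser = parse_minmax_description,
) -> EventThumbnail:
    """Read a multi-frame thumbnail TIFF into an (un-rescaled) EventThumbnail.

    ``channel_map`` maps TIFF frame index to channel name and must cover all
    four channels; channel order is configuration, never assumed.  Frames with
    no parseable min/max header fall back to the full stored range
    ``(0, 2**bit_depth - 1)`` with a logged warning.  8-bit frames are loaded
    un-rescaled; 16-bit containers are treated as native 12-bit acquisitions
    already on the true intensity scale.
    """
    path = Path(path)
    if sorted(channel_map.values()) != sorted(CHANNELS):
        raise ConfigurationError(
            f"channel_map must cover exactly {CHANNELS}, got {dict(channel_map)}"
        )
    try:
        with tifffile.TiffFile(path) as tif:
            pages = list(tif.pages)
            n_pages = len(pages)
            if n_pages != len(channel_map):
                raise ConfigurationError(
                    f"{path}: {n_pages} TIFF frames but channel_map declares "
                    f"{len(channel_map)}"
                )
            frames: dict[str, FluorescentFrame] = {}
            for idx, channel in channel_map.items():
                if not 0 <= idx < n_pages:
                    raise ConfigurationError(
                        f"{path}: channel_map index {idx} outside 0..{n_pages - 1}"
                    )
                page = pages[idx]
                px = page.asarray()
                if px.ndim != 2 or px.size == 0:
                    raise FormatError(f"{path}: frame {idx} is not a non-empty 2-D image")
                bit_depth = 8 if px.dtype.itemsize == 1 else 12
                parsed = header_parser(page.description)
                if parsed is None:
                    fallback_max = float(2**bit_depth - 1)
                    logger.warning(
                        "%s frame %d (%s): no min/max header found; "
                        "falling back to (0, %d)",
                        path, idx, channel, int(fallback_max),
                    )
                    header_min, header_max = 0.0, fallback_max
                else:
                    header_min, header_max = parsed
                frames[channel] = FluorescentFrame(
                    channel_name=channel,
                    pixels=px.astype(np.float64),
                    stored_bit_depth=bit_depth,
                    header_min=header_min,
                    header_max=header_max,
                    pixel_size_um=pixel_size_um,
                    # native 12-bit frames already carry true intensities
                    is_rescaled=(bit_depth == 12),
                )
    except (ConfigurationError, FormatError):
        raise
    except Exception as exc:  # noqa: BLE001 - surface the path in the error
        raise OSError(f"cannot read TIFF thumbnail {path}: {exc}") from exc
    return EventThumbnail(
        event_id=event_id if event_id is not None else path.stem,
        sample_id=sample_id,
        patient_id=patient_id,
        frames=frames,
    )


def rescale_frame(frame: FluorescentFrame) -> FluorescentFrame:
    """Restore an archived 8-bit frame to its true 12-bit intensity scale.

    Applies the pixel-wise affine map
    ``p -> header_min + p * (header_max - header_min) / 255``.
    Values are kept as floats (no re-quantization) so downstream thresholding
    on means is not distorted.
    """
    if frame.is_rescaled:
        raise StateError("frame is already rescaled")
    if frame.stored_bit_depth != 8:
        raise StateError("only archived 8-bit frames can be rescaled")
    if frame.header_max < frame.header_min:
        raise FormatError("header_max < header_min")
    span = frame.header_max - frame.header_min
    restored = frame.header_min + frame.pixels.astype(np.float64) * (span / 255.0)
    return replace(frame, pixels=restored, is_rescaled=True)


def ensure_rescaled(frame: FluorescentFrame) -> FluorescentFrame:
    """Rescale an archived frame; pass native/already-restored frames through."""
    return frame if frame.is_rescaled else rescale_frame(frame)


class ScoreRecord(NamedTuple):
    """One manual call: ordinal rank (0..3) or binary 'positive'/'negative'."""

    event_id: str
    scorer_id: str
    kind: str  # 'ordinal' | 'binary'
    value: int | str


def read_score_table(path: str | Path) -> list[ScoreRecord]:
    """Read a per-event manual score CSV (``event_id,scorer_id,score``).

    Ordinal tokens {0, 1+, 2+, 3+} map to ranks 0..3; binary tokens are
    'positive'/'negative' (case-insensitive).  Unknown tokens raise a
    :class:`ParseError` naming the row.
    """
    path = Path(path)
    records: list[ScoreRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"event_id", "scorer_id", "score"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: header must declare columns {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            token = (row["score"] or "").strip()
            if token in ORDINAL_TOKENS:
                rec = ScoreRecord(row["event_id"], row["scorer_id"], "ordinal",
                                  ORDINAL_TOKENS[token])
            elif token.lower() in BINARY_TOKENS:
                rec = ScoreRecord(row["event_id"], row["scorer_id"], "binary",
                                  token.lower())
            else:
                raise ParseError(f"unknown score token {token!r}", row=rownum)
            records.append(rec)
    return records


def write_thumbnail_tiff(
    path: str | Path,
    pages: Sequence[np.ndarray],
    headers: Sequence[tuple[int, int]],
) -> None:
    """Write 8-bit pages with per-page ``min=..;max=..`` ImageDescription tags.

    Counterpart of :func:`load_thumbnail` for the package's own archive
    convention; used by the synthetic-fixture generator.
    """
    if len(pages) != len(headers):
        raise ConfigurationError("one (min, max) header required per page")
    path = Path(path)
    with tifffile.TiffWriter(path) as writer:
        for page, (mn, mx) in zip(pages, headers):
            writer.write(
                np.asarray(page, dtype=np.uint8),
                description=f"min={int(mn)};max={int(mx)}",
                contiguous=False,
            )
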