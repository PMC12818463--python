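"""Probe montage: optode layout, channel roster, and region-of-interest map.

The default montage mirrors a bilateral language/auditory probe: 16 LED
sources and 14 long-channel detectors on 10-10 scalp positions forming 38
long (~30 mm) channels over bilateral inferior frontal gyrus (IFG) and
primary/secondary auditory cortex, plus 8 short-separation (8 mm) detectors
bundled at source positions to sample extracerebral scalp hemodynamics.

Template scalp coordinates are computed from the standard 10-10 angular
layout on a spherical head (radius 85 mm, MNI-like millimetre axes:
+x right, +y anterior, +z superior).  They are a geometric template, not an
empirical digitization; per-subject digitized scans are produced by the
synthetic-data module by perturbing this template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Channel",
    "MontageSpec",
    "make_montage",
    "template_positions",
    "ROIS",
    "HEAD_RADIUS_MM",
]

HEAD_RADIUS_MM = 85.0

ROIS = ("IFG_L", "IFG_R", "A1_L", "A1_R", "A2_L", "A2_R")

FIDUCIAL_NAMES = ("Nz", "Iz", "Cz", "LPA", "RPA")


def _sph(elev_deg: float, az_deg: float, radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Point on the head sphere. Elevation from the Nz-LPA-Iz-RPA equator,
    azimuth 0 at the nasion, positive toward the right ear."""
    e = np.deg2rad(elev_deg)
    a = np.deg2rad(az_deg)
    return radius * np.array([np.cos(e) * np.sin(a), np.cos(e) * np.cos(a), np.sin(e)])


def _circumcenter(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    # Circumcenter of three points in 3-D (barycentric formula).
    a = p1 - p3
    b = p2 - p3
    cross = np.cross(a, b)
    denom = 2.0 * np.dot(cross, cross)
    num = np.cross(np.dot(a, a) * b - np.dot(b, b) * a, cross)
    return p3 - num / denom


def _arc_point(start: np.ndarray, mid: np.ndarray, frac: float) -> np.ndarray:
    """Point at fraction `frac` along the circular arc from `start` to `mid`
    on the circle through (start, mid, mirror-of-start)."""
    mirror = start * np.array([-1.0, 1.0, 1.0])
    c = _circumcenter(start, mid, mirror)
    u = start - c
    v = mid - c
    axis = np.cross(u, v)
    axis = axis / np.linalg.norm(axis)
    ang = frac * np.arccos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    # Rodrigues rotation of u about axis by ang
    rot = (
        u * np.cos(ang)
        + np.cross(axis, u) * np.sin(ang)
        + axis * np.dot(axis, u) * (1 - np.cos(ang))
    )
    return c + rot


def _mirror_label(label: str) -> str:
    """Left 10-10 label -> homologous right label (odd -> even index)."""
    out = []
    for ch in label:
        if ch.isdigit():
            out.append(str(int(ch) + 1))
        else:
            out.append(ch)
    return "".join(out)


def template_positions() -> dict[str, np.ndarray]:
    """10-10 template coordinates (mm) for every label the default montage
    uses, plus the five fiducials."""
    pos: dict[str, np.ndarray] = {}
    # fiducials
    pos["Nz"] = _sph(0, 0)
    pos["Iz"] = _sph(0, 180)
    pos["Cz"] = _sph(90, 0)
    pos["LPA"] = _sph(0, -90)
    pos["RPA"] = _sph(0, 90)
    # outer 10% ring (elevation 18 deg), left hemisphere azimuths
    ring = {"AF7": -36, "F7": -54, "FT7": -72, "T7": -90, "TP7": -108, "P7": -126}
    for lab, az in ring.items():
        pos[lab] = _sph(18, az)
        pos[_mirror_label(lab)] = _sph(18, -az)
    # coronal central chain
    pos["C5"] = _sph(36, -90)
    pos["C6"] = _sph(36, 90)
    # midline anchors for the lateral chains
    fz, fcz, cpz, pz = _sph(54, 0), _sph(72, 0), _sph(72, 180), _sph(54, 180)
    chains = {
        # chain: (left endpoint, midline anchor, {label: fraction of endpoint->midline arc})
        "F": (pos["F7"], fz, {"F5": 0.25, "F3": 0.5}),
        "FC": (pos["FT7"], fcz, {"FC5": 0.25, "FC3": 0.5}),
        "CP": (pos["TP7"], cpz, {"CP7": 0.125, "CP5": 0.25, "CP3": 0.5}),
        "P": (pos["P7"], pz, {"P5": 0.25, "P3": 0.5}),
    }
    for start, mid, labels in chains.values():
        for lab, frac in labels.items():
            p = _arc_point(start, mid, frac)
            pos[lab] = p
            pos[_mirror_label(lab)] = p * np.array([-1.0, 1.0, 1.0])
    return pos


# Default long channels, left hemisphere: (source, detector, ROI).
_LEFT_PAIRS = [
    ("AF7", "F5", "IFG_L"),
    ("F7", "F5", "IFG_L"),
    ("F3", "F5", "IFG_L"),
    ("F3", "FC3", "IFG_L"),
    ("FC5", "F5", "IFG_L"),
    ("FC5", "FC3", "IFG_L"),
    ("T7", "C5", "A1_L"),
    ("FC5", "C5", "A1_L"),
    ("T7", "TP7", "A1_L"),
    ("CP5", "C5", "A1_L"),
    ("CP5", "TP7", "A1_L"),
    ("CP5", "CP7", "A1_L"),
    ("P7", "TP7", "A2_L"),
    ("P7", "CP7", "A2_L"),
    ("P7", "P5", "A2_L"),
    ("P3", "P5", "A2_L"),
    ("P3", "CP3", "A2_L"),
    ("P3", "CP7", "A2_L"),
    ("CP5", "CP3", "A2_L"),
]

SHORT_SOURCE_POSITIONS = ("F3", "FC5", "CP5", "P3", "F4", "FC6", "CP6", "P4")

DEFAULT_SOURCES = (
    "AF7", "F7", "F3", "FC5", "T7", "CP5", "P7", "P3",
    "AF8", "F8", "F4", "FC6", "T8", "CP6", "P8", "P4",
)
DEFAULT_DETECTORS = (
    "F5", "FC3", "C5", "TP7", "CP7", "CP3", "P5",
    "F6", "FC4", "C6", "TP8", "CP8", "CP4", "P6",
)

LONG_SEPARATION_MM = 30.0
SHORT_SEPARATION_MM = 8.0


@dataclass(frozen=True)
class Channel:
    source: str
    detector: str
    separation_mm: float
    kind: str  # "long" | "short"

    @property
    def name(self) -> str:
        return f"{self.source}-{self.detector}"


@dataclass
class MontageSpec:
    """Optode roster, channel list, and channel -> ROI assignment."""

    source_names: list[str]
    detector_names: list[str]
    long_channels: list[Channel]
    short_channels: list[Channel]
    roi_map: dict[str, str]
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        srcs, dets = set(self.source_names), set(self.detector_names)
        for ch in self.long_channels + self.short_channels:
            if ch.source not in srcs:
                raise ValueError(f"channel {ch.name} references undeclared source {ch.source}")
            if ch.detector not in dets:
                raise ValueError(f"channel {ch.name} references undeclared detector {ch.detector}")
        for ch in self.short_channels:
            if ch.separation_mm != SHORT_SEPARATION_MM:
                raise ValueError("short channels must have 8 mm separation")
        for ch in self.long_channels:
            if ch.name not in self.roi_map:
                raise ValueError(f"long channel {ch.name} has no ROI assignment")

    @property
    def channels(self) -> list[Channel]:
        return self.long_channels + self.short_channels

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def long_names(self) -> list[str]:
        return [c.name for c in self.long_channels]

    @property
    def short_names(self) -> list[str]:
        return [c.name for c in self.short_channels]

    def separations_mm(self) -> np.ndarray:
        return np.array([c.separation_mm for c in self.channels])

    def optode_names(self) -> list[str]:
        return list(self.source_names) + list(self.detector_names)


def make_montage(config: dict | None = None) -> MontageSpec:
    """Build the study montage.

    Without a config this returns the default bilateral probe: 38 long
    channels (19 per hemisphere) over six ROIs and 8 short channels at
    F3, FC5, CP5, P3 and their right homologues.

    A config dict may override the roster with keys ``sources``,
    ``detectors`` (lists of 10-10 labels), ``pairs`` (list of
    ``(source, detector, roi)``), and optionally ``short_sources``.
    """
    pos = template_positions()
    if config is None:
        pairs = list(_LEFT_PAIRS) + [
            (_mirror_label(s), _mirror_label(d), roi.replace("_L", "_R"))
            for s, d, roi in _LEFT_PAIRS
        ]
        sources = list(DEFAULT_SOURCES)
        detectors = list(DEFAULT_DETECTORS)
        short_sources = list(SHORT_SOURCE_POSITIONS)
    else:
        sources = list(config["sources"])
        detectors = list(config["detectors"])
        pairs = [tuple(p) for p in config["pairs"]]
        short_sources = list(config.get("short_sources", []))

    for lab in sources + detectors:
        if lab not in pos:
            raise ValueError(f"unknown 10-10 position label: {lab}")

    long_channels = []
    roi_map = {}
    for s, d, roi in pairs:
        ch = Channel(s, d, LONG_SEPARATION_MM, "long")
        long_channels.append(ch)
        roi_map[ch.name] = roi

    short_channels = []
    for s in short_sources:
        det = f"{s}h"  # bundled short-separation detector next to the source
        detectors.append(det)
        # place the short detector 8 mm from the source along the scalp tangent
        p = pos[s]
        tangent = np.cross(p, [0.0, 0.0, 1.0])
        norm = np.linalg.norm(tangent)
        tangent = tangent / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        pos[det] = p + SHORT_SEPARATION_MM * tangent
        short_channels.append(Channel(s, det, SHORT_SEPARATION_MM, "short"))

    used = {lab for c in long_channels + short_channels for lab in (c.source, c.detector)}
    positions = {lab: pos[lab] for lab in list(used) + list(FIDUCIAL_NAMES)}
    return MontageSpec(sources, detectors, long_channels, short_channels, roi_map, positions)
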