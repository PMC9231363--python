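"""Electrode montages and spatial region maps.

Regional smoothing shares one intra-block correlation matrix across all
channels of a scalp region, exploiting volume conduction: neighbouring
electrodes see temporally similar activity.  A :class:`RegionMap` is a strict
partition of the channel set into regions of at least three channels.  Two
built-in 13-region schemes are shipped (64- and 59-channel 10-20 montages);
they follow standard 10-20 neighbourhoods (prefrontal, frontal strips,
central strips, temporal, centro-parietal, parietal, parieto-occipital) and
are meant as sensible defaults that users replace with their own grouping
files when the cap layout differs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Montage", "RegionMap", "standard_montage", "builtin_region_map",
    "load_montage", "load_region_map", "save_region_map", "auto_region_map",
]

# 64-channel cap of the BCI-competition era (10-10 extension of 10-20).
_NAMES_64 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T9", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "T10",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]
# 59-EEG-channel wireless cap (64 sites minus midline/outer rim positions
# given over to reference and physiological channels).
_DROP_59 = {"Fpz", "AFz", "T9", "T10", "Iz"}
_NAMES_59 = [n for n in _NAMES_64 if n not in _DROP_59]

# Anterior-posterior position of each 10-20 band (unit head circle).
_BAND_Y = {
    "Fp": 0.85, "AF": 0.65, "F": 0.45, "FT": 0.25, "FC": 0.25,
    "T": 0.0, "C": 0.0, "TP": -0.25, "CP": -0.25,
    "P": -0.45, "PO": -0.65, "O": -0.85, "I": -1.0,
}
_LABEL_RE = re.compile(r"^(Fp|AF|FT|FC|TP|CP|PO|F|T|C|P|O|I)(z|\d+)$")


def _label_coords(name: str) -> tuple[float, float]:
    """Approximate 2-D scalp-projection coordinates from a 10-20 label."""
    m = _LABEL_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse 10-20 label {name!r}")
    band, pos = m.groups()
    y = _BAND_Y[band]
    if pos == "z":
        return 0.0, y
    d = int(pos)
    lateral = (d + 1) // 2          # 1,2->1  3,4->2  5,6->3  7,8->4  9,10->5
    x = 0.2 * lateral * (-1 if d % 2 == 1 else 1)
    return x, y


@dataclass(frozen=True)
class Montage:
    """Named electrode set with 2-D scalp coordinates."""

    channel_names: tuple[str, ...]
    coords: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        if len(set(names)) != len(names):
            raise ValueError("montage channel names must be unique")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(names), 2) or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be a finite (n_channels, 2) array")
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "coords", coords)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


def standard_montage(n_channels: int = 64) -> Montage:
    """Built-in 64- or 59-channel 10-20 montage with approximate coordinates."""
    if n_channels == 64:
        names = _NAMES_64
    elif n_channels == 59:
        names = _NAMES_59
    else:
        raise ValueError("built-in montages exist for 64 and 59 channels")
    coords = np.array([_label_coords(n) for n in names])
    return Montage(tuple(names), coords)


class RegionMap:
    """Strict partition of channel indices into spatial regions.

    Every region must contain at least three channels so that the averaged
    intra-block correlation matrix of a region pools several blocks.
    """

    def __init__(self, regions: list[list[int]], n_channels: int,
                 name: str = "custom") -> None:
        regions = [sorted(int(c) for c in r) for r in regions]
        seen: dict[int, int] = {}
        for ri, r in enumerate(regions):
            if len(r) < 3:
                raise ValueError(f"region {ri} has {len(r)} channels; minimum is 3")
            for c in r:
                if c < 0 or c >= n_channels:
                    raise ValueError(f"channel index {c} out of range")
                if c in seen:
                    raise ValueError(
                        f"channel {c} assigned to regions {seen[c]} and {ri}")
                seen[c] = ri
        missing = sorted(set(range(n_channels)) - set(seen))
        if missing:
            raise ValueError(f"channels not assigned to any region: {missing}")
        self.regions = regions
        self.n_channels = int(n_channels)
        self.name = name

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def sizes(self) -> list[int]:
        return [len(r) for r in self.regions]

    @property
    def region_of(self) -> np.ndarray:
        """Total channel -> region lookup (length n_channels)."""
        out = np.empty(self.n_channels, dtype=int)
        for ri, r in enumerate(self.regions):
            out[r] = ri
        return out

    @classmethod
    def single(cls, n_channels: int) -> "RegionMap":
        """All channels in one region (the fully shared-B degenerate map)."""
        return cls([list(range(n_channels))], n_channels, name="single")

    @classmethod
    def uniform(cls, n_channels: int, n_regions: int) -> "RegionMap":
        """Contiguous equal-split partition, handy for simulation studies."""
        bounds = np.linspace(0, n_channels, n_regions + 1).astype(int)
        regions = [list(range(bounds[i], bounds[i + 1])) for i in range(n_regions)]
        return cls(regions, n_channels, name=f"uniform{n_regions}")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"RegionMap(name={self.name!r}, n_regions={self.n_regions}, "
                f"sizes={self.sizes})")


_SCHEME_64 = {
    "prefrontal": ["Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8"],
    "frontal-left": ["F7", "F5", "F3"],
    "frontal-mid": ["F1", "Fz", "F2"],
    "frontal-right": ["F4", "F6", "F8"],
    "frontocentral-left": ["FT7", "FC5", "FC3"],
    "frontocentral-mid": ["FC1", "FCz", "FC2"],
    "frontocentral-right": ["FC4", "FC6", "FT8"],
    "central-left": ["T9", "T7", "C5", "C3"],
    "central-mid": ["C1", "Cz", "C2"],
    "central-right": ["C4", "C6", "T8", "T10"],
    "centroparietal": ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4",
                       "CP6", "TP8"],
    "parietal": ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"],
    "parieto-occipital": ["PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz",
                          "O2", "Iz"],
}


def builtin_region_map(montage: Montage) -> RegionMap:
    """13-region 10-20 neighbourhood scheme for a built-in montage."""
    names = set(montage.channel_names)
    regions = []
    for members in _SCHEME_64.values():
        kept = [montage.index(n) for n in members if n in names]
        regions.append(kept)
    if any(len(r) < 3 for r in regions):
        raise ValueError("montage does not cover the built-in scheme")
    return RegionMap(regions, montage.n_channels,
                     name=f"builtin13-{montage.n_channels}")


def load_montage(path) -> Montage:
    """Read a montage file: one ``name x y`` triple per line ('#' comments)."""
    names, coords = [], []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise ValueError(f"montage line needs 'name x y': {line!r}")
        names.append(parts[0])
        coords.append((float(parts[1]), float(parts[2])))
    return Montage(tuple(names), np.array(coords))


def load_region_map(path, montage: Montage) -> RegionMap:
    """Read a region file: one region per line, comma-separated channel names.

    An optional ``label:`` prefix names the region.  The file must assign
    every montage channel to exactly one region of >= 3 channels.
    """
    regions = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" in line:
            line = line.split(":", 1)[1]
        members = [tok.strip() for tok in line.split(",") if tok.strip()]
        unknown = [m for m in members if m not in montage.channel_names]
        if unknown:
            raise ValueError(f"unknown channels in region file: {unknown}")
        regions.append([montage.index(m) for m in members])
    return RegionMap(regions, montage.n_channels, name=str(path))


def save_region_map(path, region_map: RegionMap, montage: Montage) -> None:
    lines = []
    for ri, r in enumerate(region_map.regions):
        names = ", ".join(montage.channel_names[c] for c in r)
        lines.append(f"region{ri}: {names}")
    Path(path).write_text("\n".join(lines) + "\n")


def auto_region_map(montage: Montage, k_regions: int, seed: int = 0) -> RegionMap:
    """Deterministic spatial clustering of a montage into ``k_regions``.

    K-means on the 2-D coordinates, then undersized clusters (< 3 channels)
    are merged into their nearest neighbouring cluster by centroid distance
    until every region has at least three members.
    """
    from sklearn.cluster import KMeans

    k = int(k_regions)
    if k < 1 or montage.n_channels < 3 * k:
        raise ValueError(
            f"need at least {3 * k} channels for {k} regions of >= 3")
    if k == 1:
        return RegionMap.single(montage.n_channels)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    labels = km.fit_predict(montage.coords)
    clusters = {ci: list(np.where(labels == ci)[0]) for ci in range(k)}
    # merge undersized clusters into the nearest adequately sized neighbour
    while True:
        small = [ci for ci, mem in clusters.items() if 0 < len(mem) < 3]
        if not small:
            break
        ci = min(small, key=lambda c: len(clusters[c]))
        cen = montage.coords[clusters[ci]].mean(axis=0)
        others = [cj for cj in clusters if cj != ci and clusters[cj]]
        tgt = min(others, key=lambda cj: float(
            np.linalg.norm(montage.coords[clusters[cj]].mean(axis=0) - cen)))
        clusters[tgt].extend(clusters[ci])
        clusters[ci] = []
    regions = [sorted(mem) for mem in clusters.values() if mem]
    return RegionMap(regions, montage.n_channels, name=f"auto{k}")
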