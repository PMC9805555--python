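"""Genome binning and segmentation I/O.

Chromatin state maps arrive as ChromHMM-style BED4 segmentations (one file
per sample).  The genome is discretized into fixed-width bins (200 bp by
default, matching the resolution at which chromatin states are typically
annotated); every downstream computation operates on per-bin state vectors.

Coordinates are 0-based, half-open throughout.  Bin ``i`` of a chromosome
covers ``[i * bin_size, (i + 1) * bin_size)``; a trailing partial bin is kept
when a chromosome length is not a multiple of the bin size.
"""

from __future__ import annotations

import colorsys
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomeIndex",
    "StateScheme",
    "StateMap",
    "SampleGroup",
    "read_chrom_sizes",
    "read_segmentation",
    "write_state_bed",
    "write_score_tracks",
]

_LABEL_RE = re.compile(r"^E?(\d+)(?:_.*)?$")


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosomes tiled by fixed-width bins.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in bp (default 200).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))

    @property
    def bins_per_chrom(self) -> np.ndarray:
        return np.array([-(-length // self.bin_size) for _, length in self.chromosomes], dtype=np.int64)

    @property
    def offsets(self) -> np.ndarray:
        """Global bin index of the first bin of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)[:-1]])

    @property
    def n_bins(self) -> int:
        """G: total number of bins across the genome."""
        return int(self.bins_per_chrom.sum())

    def chrom_index(self, chrom: str) -> int:
        for k, (name, _) in enumerate(self.chromosomes):
            if name == chrom:
                return k
        raise KeyError(f"unknown chromosome: {chrom}")

    def bin_interval(self, i: int) -> tuple[str, int, int]:
        """Map global bin index to its (chrom, start, end) interval."""
        if not 0 <= i < self.n_bins:
            raise IndexError(f"bin index {i} out of range [0, {self.n_bins})")
        offs = self.offsets
        k = int(np.searchsorted(offs, i, side="right")) - 1
        name, length = self.chromosomes[k]
        local = i - offs[k]
        start = int(local) * self.bin_size
        return name, start, min(start + self.bin_size, length)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin index of the bin containing position ``pos``."""
        k = self.chrom_index(chrom)
        length = self.chromosomes[k][1]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom}:[0,{length})")
        return int(self.offsets[k]) + pos // self.bin_size

    def interval_bins(self, chrom: str, start: int, end: int) -> range:
        """Global indices of bins overlapping ``[start, end)`` by >= 1 bp."""
        k = self.chrom_index(chrom)
        length = self.chromosomes[k][1]
        if start < 0 or end <= start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        end = min(end, length)
        if start >= length:
            return range(0)
        off = int(self.offsets[k])
        first = start // self.bin_size
        last_excl = min(-(-end // self.bin_size), int(self.bins_per_chrom[k]))
        return range(off + first, off + last_excl)


def _default_colors(S: int) -> tuple[tuple[int, int, int], ...]:
    # evenly spaced hues; deterministic fallback when no scheme colors given
    out = []
    for k in range(S):
        r, g, b = colorsys.hsv_to_rgb(k / max(S, 1), 0.75, 0.85)
        out.append((int(r * 255), int(g * 255), int(b * 255)))
    return tuple(out)


@dataclass(frozen=True)
class StateScheme:
    """A chromatin state alphabet: S states with labels and optional colors.

    Labels follow ChromHMM conventions: either ``E<k>`` or ``<k>_Mnemonic``
    (e.g. ``1_TssA``, ``18_Quies``); label ``k`` resolves to integer state
    index ``k`` (1-based).
    """

    names: tuple[str, ...]
    colors: tuple[tuple[int, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("a state scheme needs at least 2 states")
        if len(set(self.names)) != len(self.names):
            raise ValueError("state names must be unique")
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if self.colors is not None:
            if len(self.colors) != len(self.names):
                raise ValueError("colors must match number of states")
            object.__setattr__(self, "colors", tuple(tuple(int(c) for c in rgb) for rgb in self.colors))

    @property
    def S(self) -> int:
        return len(self.names)

    @classmethod
    def from_n_states(cls, S: int) -> "StateScheme":
        return cls(names=tuple(f"E{k}" for k in range(1, S + 1)))

    @classmethod
    def from_file(cls, path: str | Path) -> "StateScheme":
        """Read a mnemonics table: one state per line, ``name`` or
        ``name<TAB>r,g,b``."""
        names, colors = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            names.append(parts[0])
            if len(parts) > 1:
                colors.append(tuple(int(x) for x in parts[1].split(",")))
        return cls(names=tuple(names), colors=tuple(colors) if colors else None)

    def resolve_label(self, label: str) -> int:
        """Resolve a BED state label to a 1-based state integer."""
        if label in self.names:
            return self.names.index(label) + 1
        m = _LABEL_RE.match(label)
        if m:
            k = int(m.group(1))
            if 1 <= k <= self.S:
                return k
        raise ValueError(f"unknown state label: {label!r}")

    def color(self, state: int) -> tuple[int, int, int]:
        cols = self.colors if self.colors is not None else _default_colors(self.S)
        return cols[state - 1]


@dataclass
class StateMap:
    """One sample's per-bin chromatin state assignment (integers 1..S)."""

    sample_id: str
    states: np.ndarray
    index: GenomeIndex
    scheme: StateScheme

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int32)
        if self.states.shape != (self.index.n_bins,):
            raise ValueError(
                f"state vector length {self.states.shape} != G={self.index.n_bins}"
            )
        if self.states.min(initial=1) < 1 or self.states.max(initial=1) > self.scheme.S:
            raise ValueError("state values must lie in 1..S")


@dataclass
class SampleGroup:
    """A named group of samples sharing one genome index and state scheme."""

    group_id: str
    members: list[StateMap]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a group needs at least one member")
        idx, scheme = self.members[0].index, self.members[0].scheme
        for m in self.members[1:]:
            if m.index != idx or m.scheme != scheme:
                raise ValueError("all members must share GenomeIndex and StateScheme")
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in group")

    @property
    def N(self) -> int:
        return len(self.members)

    @property
    def index(self) -> GenomeIndex:
        return self.members[0].index

    @property
    def scheme(self) -> StateScheme:
        return self.members[0].scheme

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.members]

    def state_matrix(self) -> np.ndarray:
        """G x N matrix of state integers, members in group order."""
        return np.stack([m.states for m in self.members], axis=1)

    def member(self, sample_id: str) -> StateMap:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(f"{sample_id!r} not in group {self.group_id!r}")

    def without(self, sample_id: str, group_id: str | None = None) -> "SampleGroup":
        rest = [m for m in self.members if m.sample_id != sample_id]
        if len(rest) == len(self.members):
            raise KeyError(f"{sample_id!r} not in group {self.group_id!r}")
        return SampleGroup(group_id or f"{self.group_id}-minus-{sample_id}", rest)


def read_chrom_sizes(path: str | Path, bin_size: int = 200) -> GenomeIndex:
    """Parse a UCSC-style chrom.sizes file (``name<TAB>length`` per line)."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 'name<TAB>length'")
        name = parts[0]
        if name in seen:
            raise ValueError(f"{path}:{ln}: duplicate chromosome {name!r}")
        seen.add(name)
        try:
            length = int(parts[1])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer length {parts[1]!r}") from None
        if length <= 0:
            raise ValueError(f"{path}:{ln}: non-positive length for {name}")
        chroms.append((name, length))
    if not chroms:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeIndex(chromosomes=tuple(chroms), bin_size=bin_size)


def read_segmentation(
    path: str | Path,
    index: GenomeIndex,
    scheme: StateScheme,
    sample_id: str | None = None,
    fill_state: int | None = None,
) -> StateMap:
    """Parse a BED4 segmentation into a binned state map.

    Each bin takes the state of the record covering the bin's *start*
    coordinate (deterministic for records not aligned to the bin grid).
    Bins covered by no record are an error unless ``fill_state`` is given.
    """
    path = Path(path)
    states = np.zeros(index.n_bins, dtype=np.int32)
    offs = index.offsets
    nb = index.bins_per_chrom
    bs = index.bin_size
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected >=4 BED columns")
        chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
        try:
            k = index.chrom_index(chrom)
        except KeyError:
            raise ValueError(f"{path}:{ln}: chromosome {chrom!r} not in genome index") from None
        state = scheme.resolve_label(label)
        if end <= start:
            raise ValueError(f"{path}:{ln}: empty interval")
        # bins whose start coordinate b*bs falls in [start, end)
        first = -(-start // bs)
        last_excl = min(-(-end // bs), int(nb[k]))
        if last_excl <= first:
            continue
        sl = slice(int(offs[k]) + first, int(offs[k]) + last_excl)
        if np.any(states[sl] != 0):
            raise ValueError(f"{path}:{ln}: overlapping records at {chrom}:{start}-{end}")
        states[sl] = state
    uncovered = np.flatnonzero(states == 0)
    if uncovered.size:
        if fill_state is not None:
            if not 1 <= fill_state <= scheme.S:
                raise ValueError("fill_state outside 1..S")
            states[uncovered] = fill_state
        else:
            chrom, s, e = index.bin_interval(int(uncovered[0]))
            raise ValueError(
                f"{path}: {uncovered.size} bins uncovered; first at {chrom}:{s}-{e} "
                "(pass fill_state to assign a default)"
            )
    return StateMap(sample_id=sample_id or path.stem, states=states, index=index, scheme=scheme)


def _runs(values: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (start, stop) index pairs of maximal constant runs."""
    if values.size == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    bounds = np.concatenate([[0], change, [values.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield int(a), int(b)


def write_state_bed(
    states: np.ndarray,
    index: GenomeIndex,
    scheme: StateScheme,
    path: str | Path,
) -> None:
    """Write a per-bin state vector as a BED9 track (itemRgb colored).

    Adjacent bins with the same state are merged; writing then re-reading via
    :func:`read_segmentation` reproduces the input vector exactly.
    """
    states = np.asarray(states, dtype=np.int32)
    if states.shape != (index.n_bins,):
        raise ValueError("state vector length must equal G")
    lines = []
    offs = index.offsets
    nb = index.bins_per_chrom
    for k, (chrom, length) in enumerate(index.chromosomes):
        vec = states[int(offs[k]): int(offs[k]) + int(nb[k])]
        for a, b in _runs(vec):
            s = scheme.names[vec[a] - 1]
            start = a * index.bin_size
            end = min(b * index.bin_size, length)
            r, g, bl = scheme.color(int(vec[a]))
            lines.append(f"{chrom}\t{start}\t{end}\t{s}\t0\t.\t{start}\t{end}\t{r},{g},{bl}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_score_tracks(
    matrix: np.ndarray,
    index: GenomeIndex,
    scheme: StateScheme,
    out_dir: str | Path,
    prefix: str = "",
    decimals: int = 4,
) -> list[Path]:
    """Write one bedGraph per state from a G x S score matrix.

    Values are formatted to ``decimals`` places; consecutive bins whose
    formatted values coincide are merged into one record.  Works for both
    probabilities ([0, 1]) and signed differential scores ([-1, 1]).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != scheme.S:
        raise ValueError("matrix must be G x S")
    if matrix.size and not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite values")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if matrix.shape[0] == 0:  # degenerate: no bins -> S empty tracks
        paths = []
        for s in range(scheme.S):
            p = out_dir / f"{prefix}{scheme.names[s]}.bedGraph"
            p.write_text("")
            paths.append(p)
        return paths
    if matrix.shape[0] != index.n_bins:
        raise ValueError("matrix row count must equal G")
    offs = index.offsets
    nb = index.bins_per_chrom
    paths = []
    for s in range(scheme.S):
        p = out_dir / f"{prefix}{scheme.names[s]}.bedGraph"
        lines = []
        col = np.round(matrix[:, s], decimals) + 0.0  # +0.0 normalizes -0.0
        for k, (chrom, length) in enumerate(index.chromosomes):
            vec = col[int(offs[k]): int(offs[k]) + int(nb[k])]
            for a, b in _runs(vec):
                start = a * index.bin_size
                end = min(b * index.bin_size, length)
                lines.append(f"{chrom}\t{start}\t{end}\t{vec[a]:.{decimals}f}")
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(p)
    return paths
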