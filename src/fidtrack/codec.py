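"""Square binary fiducial markers: dictionary generation, encoding, rendering.

A marker is a square grid of black/white cells (default 4x4, i.e. a 16-bit
code word) surrounded by one ring of black border cells and a white quiet
zone.  Identity is recovered by matching the sampled grid against every code
word of a *dictionary* under all four in-plane rotations, so dictionaries
are built with a rotation-invariant Hamming-distance floor and with every
code distinct from its own rotations (otherwise orientation would be
ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "MarkerCode",
    "MarkerDictionary",
    "generate_dictionary",
    "rotate_code",
    "rotation_invariant_distance",
    "render_marker",
    "render_collar_strip",
]


def _bits_from_word(word: int, grid_size: int) -> np.ndarray:
    """Unpack an integer code word into a row-major binary grid (MSB first)."""
    n = grid_size * grid_size
    if not 0 <= word < (1 << n):
        raise ValueError(f"code word {word} does not fit in {n} bits")
    bits = [(word >> (n - 1 - i)) & 1 for i in range(n)]
    return np.array(bits, dtype=np.uint8).reshape(grid_size, grid_size)


def _word_from_bits(bits: np.ndarray) -> int:
    flat = np.asarray(bits, dtype=np.uint8).ravel()
    word = 0
    for b in flat:
        word = (word << 1) | int(b)
    return word


@dataclass(frozen=True)
class MarkerCode:
    """One dictionary entry: an integer id and its binary cell grid.

    ``bits`` is row-major with 1 = white cell, 0 = black cell.  The grid is
    reproducible from the packed integer ``word`` (MSB = top-left cell).
    """

    id: int
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 2 or bits.shape[0] != bits.shape[1]:
            raise ValueError("bits must be a square 2D grid")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be binary")
        if self.id < 0:
            raise ValueError("id must be >= 0")
        object.__setattr__(self, "bits", bits)
        self.bits.setflags(write=False)

    @property
    def word(self) -> int:
        return _word_from_bits(self.bits)

    @property
    def grid_size(self) -> int:
        return self.bits.shape[0]


def rotate_code(bits: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Rotate a cell grid clockwise by ``quarter_turns`` * 90 degrees."""
    if quarter_turns not in (0, 1, 2, 3):
        raise ValueError("quarter_turns must be in {0, 1, 2, 3}")
    return np.rot90(np.asarray(bits), -quarter_turns)


def rotation_invariant_distance(a, b) -> int:
    """Minimum Hamming distance between ``a`` and the four rotations of ``b``.

    Accepts MarkerCode instances or raw grids of equal size.
    """
    ga = a.bits if isinstance(a, MarkerCode) else np.asarray(a, dtype=np.uint8)
    gb = b.bits if isinstance(b, MarkerCode) else np.asarray(b, dtype=np.uint8)
    if ga.shape != gb.shape:
        raise ValueError("grids must share a grid size")
    return min(int((ga != rotate_code(gb, r)).sum()) for r in range(4))


@dataclass
class MarkerDictionary:
    """Ordered set of marker codes with rotation-distinctness guarantees."""

    codes: list[MarkerCode]
    grid_size: int = 4
    min_distance: int = 1
    seed: int = 0

    def __len__(self) -> int:
        return len(self.codes)

    def __getitem__(self, idx: int) -> MarkerCode:
        return self.codes[idx]

    def validate(self) -> None:
        """Exhaustively check all dictionary invariants; raise on violation."""
        for c in self.codes:
            if c.grid_size != self.grid_size:
                raise ValueError(f"code {c.id} has wrong grid size")
            for r in (1, 2, 3):
                if np.array_equal(c.bits, rotate_code(c.bits, r)):
                    raise ValueError(f"code {c.id} equals its own rotation {r}")
        for i, a in enumerate(self.codes):
            for b in self.codes[i + 1:]:
                d = rotation_invariant_distance(a, b)
                if d < self.min_distance:
                    raise ValueError(
                        f"codes {a.id}/{b.id} at rotation-invariant distance "
                        f"{d} < {self.min_distance}"
                    )

    # -- plain-text serialization -------------------------------------
    def to_dict(self) -> dict:
        return {
            "grid_size": self.grid_size,
            "min_distance": self.min_distance,
            "seed": self.seed,
            "codes": [int(c.word) for c in self.codes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerDictionary":
        gs = int(d["grid_size"])
        codes = [MarkerCode(i, _bits_from_word(int(w), gs))
                 for i, w in enumerate(d["codes"])]
        return cls(codes=codes, grid_size=gs,
                   min_distance=int(d.get("min_distance", 1)),
                   seed=int(d.get("seed", 0)))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "MarkerDictionary":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def generate_dictionary(n_markers: int, grid_size: int = 4,
                        min_distance: int = 1, seed: int = 0,
                        max_draws: int = 200_000) -> MarkerDictionary:
    """Generate a marker dictionary by seeded rejection sampling.

    Random code words are drawn and accepted when (a) all four rotations of
    the candidate are mutually distinct (so orientation is resolvable) and
    (b) the rotation-invariant Hamming distance to every accepted code is at
    least ``min_distance``.  Deterministic for a fixed seed.

    Raises ``RuntimeError`` if the constraint set cannot be satisfied within
    ``max_draws`` candidate draws.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")

    rng = np.random.default_rng(seed)
    accepted: list[MarkerCode] = []
    draws = 0
    while len(accepted) < n_markers:
        if draws >= max_draws:
            raise RuntimeError(
                f"dictionary generation infeasible: only {len(accepted)} of "
                f"{n_markers} codes found after {max_draws} draws "
                f"(grid_size={grid_size}, min_distance={min_distance})"
            )
        draws += 1
        bits = rng.integers(0, 2, size=(grid_size, grid_size), dtype=np.uint8)
        rots = [rotate_code(bits, r) for r in range(4)]
        if any(np.array_equal(rots[0], rots[r]) for r in (1, 2, 3)):
            continue
        # rotations must also be pairwise distinct among themselves
        if (np.array_equal(rots[1], rots[3]) or np.array_equal(rots[1], rots[2])
                or np.array_equal(rots[2], rots[3])):
            continue
        if any(rotation_invariant_distance(c.bits, bits) < min_distance
               for c in accepted):
            continue
        accepted.append(MarkerCode(len(accepted), bits))
    return MarkerDictionary(codes=accepted, grid_size=grid_size,
                            min_distance=min_distance, seed=seed)


def render_marker(dictionary: MarkerDictionary, marker_id: int,
                  cell_px: int = 10, quiet_zone_cells: int = 1,
                  border_cells: int = 1) -> np.ndarray:
    """Render one marker as a grayscale uint8 image (0 = black, 255 = white).

    Layout from the outside in: ``quiet_zone_cells`` white rings, one ring of
    ``border_cells`` black cells, then the data grid.  The detector requires
    the white quiet zone to isolate the black border contour.
    """
    if cell_px < 1 or quiet_zone_cells < 1 or border_cells < 1:
        raise ValueError("cell_px, quiet_zone_cells and border_cells must be >= 1")
    try:
        code = dictionary[marker_id]
    except IndexError:
        raise KeyError(f"unknown marker id {marker_id}") from None
    gs = dictionary.grid_size
    side_cells = gs + 2 * border_cells + 2 * quiet_zone_cells
    cells = np.ones((side_cells, side_cells), dtype=np.uint8)  # white
    q = quiet_zone_cells
    b = border_cells
    cells[q:side_cells - q, q:side_cells - q] = 0  # black border block
    cells[q + b:q + b + gs, q + b:q + b + gs] = code.bits
    img = np.kron(cells, np.ones((cell_px, cell_px), dtype=np.uint8)) * 255
    return img


def render_collar_strip(dictionary: MarkerDictionary, marker_id: int,
                        strip_length_mm: float = 250.0,
                        strip_height_mm: float = 25.0,
                        dpi: float = 300.0) -> np.ndarray:
    """Render a printable collar sticker: one id tiled along the strip.

    The marker (including its quiet zone) is scaled so its side equals the
    strip height; repeats are laid edge to edge, their quiet zones providing
    the required white separation.  Remaining length is white.
    """
    px_per_mm = dpi / 25.4
    height_px = int(round(strip_height_mm * px_per_mm))
    length_px = int(round(strip_length_mm * px_per_mm))
    if height_px < 8:
        raise ValueError("strip height too small to render a marker")
    gs = dictionary.grid_size
    side_cells = gs + 2 + 2  # data + border + quiet rings
    cell_px = max(1, height_px // side_cells)
    tile = render_marker(dictionary, marker_id, cell_px=cell_px)
    # scale tile up to the exact strip height by nearest-neighbour
    from skimage.transform import resize
    tile = (resize(tile, (height_px, height_px), order=0,
                   preserve_range=True, anti_aliasing=False)
            .astype(np.uint8))
    n_repeats = max(1, length_px // height_px)
    strip = np.full((height_px, length_px), 255, dtype=np.uint8)
    for k in range(n_repeats):
        strip[:, k * height_px:(k + 1) * height_px] = tile
    return strip
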