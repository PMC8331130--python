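"""Per-pixel color indices derived from the raw RGB channels.

Color indices are scalar recombinations of the red, green and blue channels
that usually separate objects from background better than any raw channel
does.  The working set here is four index *families* applied to each primary
channel, twelve planes in total:

======  =============================  =========================================
family  formula (channel ``X``)        meaning
======  =============================  =========================================
PAT     ``X / (X + Y)``                proportion among two bands
DIF     ``2X - Y - Z``                 excess-channel difference (signed)
ROO     ``X / Y``                      ratio over the next channel
GLD     ``(X - Y) / (X + Z)``          asymmetric normalized contrast
======  =============================  =========================================

``Y`` is the cyclic successor of ``X`` and ``Z`` the remaining channel
(R -> G -> B -> R), so e.g. ``PAT_G = G / (G + B)``.  The families are held in
a registry keyed by plane name; :func:`register_index` swaps or extends
definitions without touching any downstream code.

All arithmetic is floating point after casting from 8-bit.  Whenever a
denominator is exactly zero the index value at that pixel is defined to be
0.0, which keeps every plane finite (this only matters for pure-black and
similar edge-case pixels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

__all__ = [
    "DEFAULT_INDEX_NAMES",
    "IndexStack",
    "IndexRegistry",
    "default_registry",
    "register_index",
    "compute_index_stack",
]

#: Guard value substituted where an index denominator is exactly zero.
GUARD_VALUE = 0.0

#: Fixed plane order of the default working set.
DEFAULT_INDEX_NAMES: Tuple[str, ...] = (
    "PAT_R", "PAT_G", "PAT_B",
    "DIF_R", "DIF_G", "DIF_B",
    "ROO_R", "ROO_G", "ROO_B",
    "GLD_R", "GLD_G", "GLD_B",
)

IndexFormula = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def _safe_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise ``num / den`` with zero denominators mapped to GUARD_VALUE."""
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.full(np.broadcast(num, den).shape, GUARD_VALUE, dtype=np.float64)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _cyclic(channel: str) -> Tuple[int, int, int]:
    # X, its cyclic successor Y, remaining channel Z
    return {"R": (0, 1, 2), "G": (1, 2, 0), "B": (2, 0, 1)}[channel]


def _make_family(family: str, channel: str) -> IndexFormula:
    ix, iy, iz = _cyclic(channel)

    def formula(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
        ch = (np.asarray(r, dtype=np.float64),
              np.asarray(g, dtype=np.float64),
              np.asarray(b, dtype=np.float64))
        x, y, z = ch[ix], ch[iy], ch[iz]
        if family == "PAT":
            return _safe_divide(x, x + y)
        if family == "DIF":
            return 2.0 * x - y - z
        if family == "ROO":
            return _safe_divide(x, y)
        if family == "GLD":
            return _safe_divide(x - y, x + z)
        raise ValueError(f"unknown index family {family!r}")

    return formula


class IndexRegistry:
    """Ordered name -> formula mapping; formulas are pure functions of (R, G, B)."""

    def __init__(self) -> None:
        self._formulas: Dict[str, IndexFormula] = {}

    def register(self, name: str, formula: IndexFormula, *, replace: bool = False) -> "IndexRegistry":
        if not callable(formula):
            raise ValueError(f"formula for index {name!r} must be callable")
        if name in self._formulas and not replace:
            raise ValueError(
                f"index {name!r} is already registered; pass replace=True to overwrite"
            )
        self._formulas[name] = formula
        return self

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self._formulas)

    def items(self):
        return self._formulas.items()

    def __len__(self) -> int:
        return len(self._formulas)

    def __contains__(self, name: str) -> bool:
        return name in self._formulas


def default_registry() -> IndexRegistry:
    """Fresh registry holding the 12 default planes in their fixed order."""
    reg = IndexRegistry()
    for family in ("PAT", "DIF", "ROO", "GLD"):
        for channel in ("R", "G", "B"):
            reg.register(f"{family}_{channel}", _make_family(family, channel))
    return reg


def register_index(
    registry: IndexRegistry, name: str, formula: IndexFormula, *, replace: bool = False
) -> IndexRegistry:
    """Add ``name = formula(R, G, B)`` to ``registry`` (module-level convenience)."""
    return registry.register(name, formula, replace=replace)


@dataclass(frozen=True)
class IndexStack:
    """``h x w x d`` block of real-valued index planes with their names."""

    data: np.ndarray  # float64, shape (h, w, d)
    names: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != len(self.names):
            raise ValueError("index data shape does not match plane names")

    @property
    def h(self) -> int:
        return self.data.shape[0]

    @property
    def w(self) -> int:
        return self.data.shape[1]

    @property
    def d(self) -> int:
        return self.data.shape[2]

    def plane(self, name: str) -> np.ndarray:
        return self.data[:, :, self.names.index(name)]


def compute_index_stack(image: np.ndarray, registry: IndexRegistry | None = None) -> IndexStack:
    """Evaluate every registered index plane per pixel of an 8-bit RGB image.

    Parameters
    ----------
    image
        ``(h, w, 3)`` array of 0-255 intensities.
    registry
        Index definitions; the default 12-plane working set when omitted.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB image")
    if registry is None:
        registry = default_registry()
    r = image[:, :, 0].astype(np.float64)
    g = image[:, :, 1].astype(np.float64)
    b = image[:, :, 2].astype(np.float64)
    planes = []
    for name, formula in registry.items():
        plane = np.asarray(formula(r, g, b), dtype=np.float64)
        if plane.shape != r.shape:
            plane = np.broadcast_to(plane, r.shape).astype(np.float64)
        if not np.all(np.isfinite(plane)):
            raise FloatingPointError(f"index plane {name!r} produced non-finite values")
        planes.append(plane)
    data = np.stack(planes, axis=-1)
    return IndexStack(data=data, names=registry.names)
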