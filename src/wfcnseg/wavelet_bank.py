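"""Multilevel 2D discrete wavelet decomposition and reconstruction.

This module is a self-contained separable 2D DWT engine over a registry of
named filter banks (Daubechies ``db1``–``db10``, Symlets ``sym2``–``sym8``,
biorthogonal splines ``bior1.1/1.3/2.2/3.1/4.4`` and ``rbio1.1/2.2``).  One
analysis level splits an even-sided image into four subbands — the
low-frequency *approximation* and the *horizontal*, *vertical* and *diagonal*
details — each of half the input side, so an image of side :math:`2^L m`
supports :math:`L` levels with approximation sides halving dyadically
(e.g. 240 → 120, 60, 30, 15).

Boundary handling is periodic (circular) extension throughout.  This keeps
subband sizes exactly dyadic, makes orthogonal kernels exactly
energy-preserving, and gives perfect reconstruction for every registered
kernel.  Conventions (matching the common *periodization* mode of reference
wavelet software, so coefficients are directly comparable):

- analysis: ``a[n] = sum_k dec_lo[k] * x[(2n + L/2 - k) mod N]`` for a filter
  of even length ``L`` on a signal of even length ``N``, likewise with
  ``dec_hi`` for the detail channel;
- synthesis: zero-upsample the two channels and circularly convolve with
  ``rec_lo``/``rec_hi`` at phase ``L/2 - 1``;
- high-pass filters follow the quadrature-mirror relations
  ``dec_hi[k] = (-1)^(k+1) rec_lo[k]`` and ``rec_hi[k] = (-1)^k dec_lo[k]``;
  for orthogonal kernels ``rec_lo`` is ``dec_lo`` time-reversed.

Grids are 2D numeric arrays, row-major, row 0 at the image top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from ._filters import BIORTHOGONAL_LO, ORTHOGONAL_DEC_LO

__all__ = [
    "WaveletKernel",
    "SubbandSet",
    "MultilevelDecomposition",
    "KernelRegistryError",
    "DimensionError",
    "KernelMismatchError",
    "get_kernel",
    "available_kernels",
    "register_kernel",
    "registry_to_json",
    "registry_from_json",
    "dwt2",
    "idwt2",
    "wavedec2",
    "waverec2",
]

_SQRT2 = float(np.sqrt(2.0))
_ORTHO_TOL = 1e-10


class KernelRegistryError(KeyError):
    """Raised when a wavelet kernel name is not in the registry."""


class DimensionError(ValueError):
    """Raised when grid sizes are incompatible with the requested transform."""


class KernelMismatchError(ValueError):
    """Raised when a decomposition is reconstructed with a different kernel."""


@dataclass(frozen=True)
class WaveletKernel:
    """A named analysis/synthesis filter quadruple.

    Parameters
    ----------
    name : str
        Kernel identifier, e.g. ``"db1"``.
    dec_lo, dec_hi : ndarray
        1D low-/high-pass analysis filters (equal even length).
    rec_lo, rec_hi : ndarray
        1D low-/high-pass synthesis filters (equal even length).
    orthogonal : bool
        True for orthonormal families (db, sym); their analysis low-pass sums
        to sqrt(2) and the high-pass has zero mean.
    """

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray
    orthogonal: bool

    def __post_init__(self) -> None:
        for attr in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
            arr = np.asarray(getattr(self, attr), dtype=np.float64)
            arr.flags.writeable = False
            object.__setattr__(self, attr, arr)
        if self.dec_lo.shape != self.dec_hi.shape:
            raise ValueError(f"{self.name}: dec_lo/dec_hi length mismatch")
        if self.rec_lo.shape != self.rec_hi.shape:
            raise ValueError(f"{self.name}: rec_lo/rec_hi length mismatch")
        if self.dec_lo.ndim != 1 or self.dec_lo.size % 2:
            raise ValueError(f"{self.name}: filters must be 1D of even length")
        if self.orthogonal:
            if abs(self.dec_lo.sum() - _SQRT2) > _ORTHO_TOL:
                raise ValueError(f"{self.name}: orthogonal dec_lo must sum to sqrt(2)")
            if abs(self.dec_hi.sum()) > _ORTHO_TOL:
                raise ValueError(f"{self.name}: orthogonal dec_hi must have zero mean")

    @property
    def filter_length(self) -> int:
        return int(self.dec_lo.size)


@dataclass(frozen=True)
class SubbandSet:
    """Four same-shape subband grids from one decomposition level."""

    approximation: np.ndarray
    horizontal: np.ndarray
    vertical: np.ndarray
    diagonal: np.ndarray
    level: int

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.grids()}
        if len(shapes) != 1:
            raise DimensionError(f"subband shapes differ: {sorted(shapes)}")
        if self.level < 1:
            raise ValueError("level must be a positive integer")

    def grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.approximation, self.horizontal, self.vertical, self.diagonal)

    @property
    def shape(self) -> tuple[int, int]:
        return self.approximation.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class MultilevelDecomposition:
    """Ordered subband sets from level 1 (finest) to level L (coarsest)."""

    kernel_name: str
    levels: tuple[SubbandSet, ...]
    input_shape: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "input_shape", tuple(self.input_shape))

    def __iter__(self) -> Iterator[SubbandSet]:
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def num_levels(self) -> int:
        return len(self.levels)

    def approximation_sides(self) -> list[int]:
        """Approximation grid side per level, finest to coarsest."""
        return [s.shape[0] for s in self.levels]


# --------------------------------------------------------------------------
# Kernel registry
# --------------------------------------------------------------------------

def _qmf_highpass(rec_lo: np.ndarray) -> np.ndarray:
    k = np.arange(rec_lo.size)
    return ((-1.0) ** (k + 1)) * rec_lo


def _qmf_rec_highpass(dec_lo: np.ndarray) -> np.ndarray:
    k = np.arange(dec_lo.size)
    return ((-1.0) ** k) * dec_lo


def _build_kernel(name: str, dec_lo: Sequence[float],
                  rec_lo: Sequence[float] | None = None) -> WaveletKernel:
    dec_lo = np.asarray(dec_lo, dtype=np.float64)
    orthogonal = rec_lo is None
    rec = dec_lo[::-1].copy() if rec_lo is None else np.asarray(rec_lo, np.float64)
    return WaveletKernel(
        name=name,
        dec_lo=dec_lo,
        dec_hi=_qmf_highpass(rec),
        rec_lo=rec,
        rec_hi=_qmf_rec_highpass(dec_lo),
        orthogonal=orthogonal,
    )


def _default_registry() -> dict[str, WaveletKernel]:
    reg: dict[str, WaveletKernel] = {}
    for name, lo in ORTHOGONAL_DEC_LO.items():
        reg[name] = _build_kernel(name, lo)
    for name, (dec, rec) in BIORTHOGONAL_LO.items():
        reg[name] = _build_kernel(name, dec, rec)
    return reg


_REGISTRY: dict[str, WaveletKernel] = _default_registry()
_ALIASES = {"haar": "db1"}


def available_kernels() -> list[str]:
    """Names of all registered kernels (aliases excluded), sorted."""
    return sorted(_REGISTRY)


def get_kernel(name: str) -> WaveletKernel:
    """Look up a kernel by name (``"haar"`` is an alias of ``"db1"``)."""
    key = _ALIASES.get(name, name)
    try:
        return _REGISTRY[key]
    except KeyError:
        raise KernelRegistryError(
            f"unknown wavelet kernel {name!r}; available: "
            f"{', '.join(available_kernels())}"
        ) from None


def register_kernel(kernel: WaveletKernel, overwrite: bool = False) -> None:
    """Add a kernel to the registry (the benchmark iterates whatever is here)."""
    if kernel.name in _REGISTRY and not overwrite:
        raise ValueError(f"kernel {kernel.name!r} already registered")
    _REGISTRY[kernel.name] = kernel


def registry_to_json(names: Sequence[str] | None = None) -> str:
    """Serialize (a subset of) the registry as a JSON document."""
    names = list(names) if names is not None else available_kernels()
    doc = {}
    for n in names:
        k = get_kernel(n)
        doc[k.name] = {
            "dec_lo": k.dec_lo.tolist(),
            "dec_hi": k.dec_hi.tolist(),
            "rec_lo": k.rec_lo.tolist(),
            "rec_hi": k.rec_hi.tolist(),
            "orthogonal": k.orthogonal,
        }
    return json.dumps(doc, indent=1)


def registry_from_json(document: str) -> dict[str, WaveletKernel]:
    """Deserialize kernels from a JSON document produced by `registry_to_json`."""
    doc = json.loads(document)
    out = {}
    for name, f in doc.items():
        out[name] = WaveletKernel(
            name=name,
            dec_lo=np.asarray(f["dec_lo"]),
            dec_hi=np.asarray(f["dec_hi"]),
            rec_lo=np.asarray(f["rec_lo"]),
            rec_hi=np.asarray(f["rec_hi"]),
            orthogonal=bool(f["orthogonal"]),
        )
    return out


def _as_kernel(kernel: WaveletKernel | str) -> WaveletKernel:
    return kernel if isinstance(kernel, WaveletKernel) else get_kernel(kernel)


# --------------------------------------------------------------------------
# 1D periodized filter-bank steps
# --------------------------------------------------------------------------

def _analysis_1d(x: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                 axis: int) -> tuple[np.ndarray, np.ndarray]:
    n_len = x.shape[axis]
    flen = lo.size
    if n_len % 2:
        raise DimensionError(f"side {n_len} along axis {axis} is odd")
    if n_len < flen:
        raise DimensionError(
            f"side {n_len} along axis {axis} is smaller than the filter "
            f"length {flen}"
        )
    half = np.arange(n_len // 2)[:, None]
    taps = np.arange(flen)[None, :]
    idx = (2 * half + flen // 2 - taps) % n_len
    xt = np.moveaxis(x, axis, 0)
    gathered = xt[idx]  # (n/2, flen, ...)
    approx = np.tensordot(gathered, lo, axes=([1], [0]))
    detail = np.tensordot(gathered, hi, axes=([1], [0]))
    return np.moveaxis(approx, 0, axis), np.moveaxis(detail, 0, axis)


def _synthesis_1d(approx: np.ndarray, detail: np.ndarray, lo: np.ndarray,
                  hi: np.ndarray, axis: int) -> np.ndarray:
    flen = lo.size
    at = np.moveaxis(approx, axis, 0)
    dt = np.moveaxis(detail, axis, 0)
    n_len = 2 * at.shape[0]
    up_a = np.zeros((n_len,) + at.shape[1:], dtype=np.result_type(at, np.float64))
    up_d = np.zeros_like(up_a)
    up_a[::2] = at
    up_d[::2] = dt
    pos = np.arange(n_len)[:, None]
    taps = np.arange(flen)[None, :]
    idx = (pos - taps + flen // 2 - 1) % n_len
    x = (np.tensordot(up_a[idx], lo, axes=([1], [0]))
         + np.tensordot(up_d[idx], hi, axes=([1], [0])))
    return np.moveaxis(x, 0, axis)


# --------------------------------------------------------------------------
# 2D transforms
# --------------------------------------------------------------------------

def dwt2(image: np.ndarray, kernel: WaveletKernel | str,
         level: int = 1) -> SubbandSet:
    """One separable 2D analysis level: rows then columns, each with dyadic
    downsampling.  Returns the four half-side subbands."""
    k = _as_kernel(kernel)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise DimensionError(f"expected a 2D grid, got ndim={img.ndim}")
    lo_rows, hi_rows = _analysis_1d(img, k.dec_lo, k.dec_hi, axis=1)
    ll, lh = _analysis_1d(lo_rows, k.dec_lo, k.dec_hi, axis=0)
    hl, hh = _analysis_1d(hi_rows, k.dec_lo, k.dec_hi, axis=0)
    return SubbandSet(approximation=ll, horizontal=lh, vertical=hl,
                      diagonal=hh, level=level)


def idwt2(subbands: SubbandSet, kernel: WaveletKernel | str) -> np.ndarray:
    """Invert one 2D analysis level (columns then rows)."""
    k = _as_kernel(kernel)
    lo_rows = _synthesis_1d(subbands.approximation, subbands.horizontal,
                            k.rec_lo, k.rec_hi, axis=0)
    hi_rows = _synthesis_1d(subbands.vertical, subbands.diagonal,
                            k.rec_lo, k.rec_hi, axis=0)
    return _synthesis_1d(lo_rows, hi_rows, k.rec_lo, k.rec_hi, axis=1)


def wavedec2(image: np.ndarray, kernel: WaveletKernel | str,
             levels: int) -> MultilevelDecomposition:
    """Multilevel 2D decomposition: level ``k+1`` transforms level ``k``'s
    approximation.  The input side must be divisible by ``2**levels``."""
    k = _as_kernel(kernel)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise DimensionError(f"expected a 2D grid, got ndim={img.ndim}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    for side in img.shape:
        if side % (1 << levels):
            raise DimensionError(
                f"input side {side} is not divisible by 2^{levels}; "
                f"level {int(np.floor(np.log2(side & -side))) + 1} would need "
                f"an odd side"
            )
    out: list[SubbandSet] = []
    current = img
    for lev in range(1, levels + 1):
        sb = dwt2(current, k, level=lev)
        out.append(sb)
        current = sb.approximation
    return MultilevelDecomposition(kernel_name=k.name, levels=tuple(out),
                                   input_shape=img.shape)


def waverec2(decomp: MultilevelDecomposition,
             kernel: WaveletKernel | str) -> np.ndarray:
    """Reconstruct the original grid from a multilevel decomposition."""
    k = _as_kernel(kernel)
    if k.name != decomp.kernel_name and _ALIASES.get(k.name) != decomp.kernel_name:
        raise KernelMismatchError(
            f"decomposition was produced with {decomp.kernel_name!r}, "
            f"reconstruction requested with {k.name!r}"
        )
    current = decomp.levels[-1].approximation
    for sb in reversed(decomp.levels):
        merged = SubbandSet(approximation=current, horizontal=sb.horizontal,
                            vertical=sb.vertical, diagonal=sb.diagonal,
                            level=sb.level)
        current = idwt2(merged, k)
    if current.shape != decomp.input_shape:
        raise DimensionError(
            f"reconstructed shape {current.shape} != recorded input shape "
            f"{decomp.input_shape}"
        )
    return current
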