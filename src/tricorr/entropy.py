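"""4D lag PDF estimation and Shannon entropy.

The summed 4D lag distribution is normalized into a maximum-likelihood
histogram PDF (cell value / total; no smoothing or pseudocounts), and the
plug-in Shannon entropy

    H = - sum_i p_i * log2(p_i)

is computed over its cells, in bits.  The PDF support is the full lag
window: structurally impossible cells simply carry probability 0 and
contribute nothing (0 * log 0 := 0).  Because normalization divides out any
constant factor, summed and averaged triple-correlation tensors yield the
same PDF and the same entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import LagTensor, LagWindow
from .errors import DegenerateInputError, InputError

__all__ = ["LagPDF", "EntropyValue", "estimate_pdf", "shannon_entropy"]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class LagPDF:
    """Normalized 4D lag distribution; same axis order as :class:`LagTensor`."""

    probs: np.ndarray
    window: LagWindow

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != self.window.shape:
            raise InputError(
                f"PDF shape {p.shape} does not match window shape {self.window.shape}"
            )
        if (p < 0).any():
            raise InputError("PDF entries must be >= 0")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise InputError(f"PDF must sum to 1 (got {p.sum()!r})")
        object.__setattr__(self, "probs", p)

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.probs))


@dataclass(frozen=True)
class EntropyValue:
    """Shannon entropy of a lag PDF.

    ``H`` is in bits unless stated otherwise; ``support_size`` counts the
    nonzero PDF cells, so ``0 <= H <= log2(support_size)``.
    """

    H: float
    support_size: int


def estimate_pdf(tensor: LagTensor) -> LagPDF:
    """Maximum-likelihood histogram normalization of a lag tensor.

    Raises
    ------
    DegenerateInputError
        If the tensor total is 0 (e.g. an empty raster): the PDF is
        undefined, never NaN.
    """
    total = float(tensor.total)
    if total <= 0:
        raise DegenerateInputError(
            "lag tensor total is 0; the lag PDF is undefined for an empty raster"
        )
    return LagPDF(np.asarray(tensor.values, dtype=float) / total, window=tensor.window)


def shannon_entropy(pdf: LagPDF, base: float = 2.0) -> EntropyValue:
    """Plug-in Shannon entropy of the 4D lag PDF.

    Zero cells contribute 0; the default base-2 logarithm reports bits.
    """
    if base <= 1:
        raise InputError("logarithm base must be > 1")
    p = pdf.probs[pdf.probs > 0]
    H = float(-(p * (np.log(p) / np.log(base))).sum())
    # clamp the tiny negative round-off a one-cell PDF can produce
    return EntropyValue(H=max(H, 0.0), support_size=int(p.size))
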