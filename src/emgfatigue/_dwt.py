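"""Minimal orthogonal discrete wavelet transform (symmetric padding).

Only what the wavelet fatigue feature needs: multilevel decomposition of a
1-D signal and reconstruction of the deep approximation back to signal
length.  Filters are the standard orthonormal Daubechies/Symlet scaling
coefficients; correctness is pinned down by the perfect-reconstruction and
orthonormality tests in the suite.
"""

from __future__ import annotations

import numpy as np

from .core import ValidationError

__all__ = ["SUPPORTED_WAVELETS", "filters", "dwt", "idwt", "approx_reconstruction"]

# Orthonormal scaling (reconstruction low-pass) filters.
_REC_LO: dict[str, tuple[float, ...]] = {
    "haar": (0.7071067811865476, 0.7071067811865476),
    "db2": (0.48296291314453414, 0.8365163037378079,
            0.22414386804185735, -0.12940952255126037),
    "db3": (0.3326705529500825, 0.8068915093110924, 0.4598775021184914,
            -0.13501102001025458, -0.08544127388202666, 0.03522629188570953),
    "db4": (0.23037781330885523, 0.7148465705525415, 0.6308807679295904,
            -0.02798376941698385, -0.18703481171888114, 0.030841381835986965,
            0.032883011666982945, -0.010597401784997278),
    "sym4": (0.0322231006040427, -0.012603967262037833, -0.09921954357684722,
             0.29785779560527736, 0.8037387518059161, 0.49761866763201545,
             -0.02963552764599851, -0.07576571478927333),
    "sym5": (0.019538882735286728, -0.021101834024758855, -0.17532808990845047,
             0.01660210576452232, 0.6339789634582119, 0.7234076904024206,
             0.1993975339773936, -0.039134249302383094, 0.029519490925774643,
             0.027333068345077982),
}

SUPPORTED_WAVELETS = frozenset(_REC_LO)


def filters(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (dec_lo, dec_hi, rec_lo, rec_hi) for a supported wavelet."""
    try:
        rec_lo = np.asarray(_REC_LO[name], dtype=float)
    except KeyError:
        raise ValidationError(
            f"unsupported wavelet {name!r}; supported: {sorted(SUPPORTED_WAVELETS)}"
        ) from None
    p = rec_lo.size
    rec_hi = np.array([(-1.0) ** k * rec_lo[p - 1 - k] for k in range(p)])
    return rec_lo[::-1].copy(), rec_hi[::-1].copy(), rec_lo, rec_hi


def dwt(x: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step with symmetric signal extension."""
    dec_lo, dec_hi, _, _ = filters(name)
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("signal too short for a DWT step")
    p = dec_lo.size
    xe = np.pad(x, p - 1, mode="symmetric")
    ca = np.convolve(xe, dec_lo, mode="valid")[1::2]
    cd = np.convolve(xe, dec_hi, mode="valid")[1::2]
    return ca, cd


def idwt(ca: np.ndarray, cd: np.ndarray | None, name: str, out_len: int) -> np.ndarray:
    """Inverse of :func:`dwt`; ``cd=None`` means an all-zero detail band."""
    _, _, rec_lo, rec_hi = filters(name)
    ca = np.asarray(ca, dtype=float)
    p = rec_lo.size
    up_a = np.zeros(2 * ca.size)
    up_a[::2] = ca
    y = np.convolve(up_a, rec_lo, mode="full")
    if cd is not None:
        cd = np.asarray(cd, dtype=float)
        up_d = np.zeros(2 * cd.size)
        up_d[::2] = cd
        y = y + np.convolve(up_d, rec_hi, mode="full")
    start = p - 2
    if start < 0 or start + out_len > y.size:
        raise ValidationError("requested output length inconsistent with coefficients")
    return y[start:start + out_len]


def approx_reconstruction(x: np.ndarray, name: str, level: int) -> np.ndarray:
    """Level-``level`` approximation of ``x``, reconstructed to ``len(x)``.

    Decomposes ``level`` times keeping only approximation coefficients, then
    reconstructs with all detail bands zeroed.
    """
    if level < 1:
        raise ValidationError("level must be >= 1")
    x = np.asarray(x, dtype=float)
    lengths = []
    ca = x
    for _ in range(level):
        lengths.append(ca.size)
        ca, _cd = dwt(ca, name)
    for out_len in reversed(lengths):
        ca = idwt(ca, None, name, out_len)
    return ca
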