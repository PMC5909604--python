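import numpy as np


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (display convention: 9.5 -> 10, -26.5 -> -27)."""
    arr = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    if arr.ndim == 0:
        return float(out)
    return out


def apportion(total: float, components) -> np.ndarray:
    """Split `total` over `components` proportionally to their signed values.

    Preserves each component's sign whenever total and the component sum share a
    sign, and the result always sums to `total` exactly (up to float addition).
    Degenerate cases: if the signed sum is zero, falls back to absolute-value
    weights; if all components are zero, splits equally (total is then ~0 in
    every use here).
    """
    comps = np.asarray(components, dtype=float)
    if comps.size == 0:
        return comps
    s = comps.sum()
    if s != 0.0:
        return comps * (total / s)
    sa = np.abs(comps).sum()
    if sa > 0.0:
        return np.abs(comps) / sa * total
    return np.full_like(comps, total / comps.size)
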