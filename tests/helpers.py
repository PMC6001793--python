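"""Shared measurement helpers for the test suite."""

import numpy as np


def measured_fwhm_hz(spec, row=0, around_index=None, zoom=1):
    """Full width at half maximum of the tallest real-part peak, Hz, by
    linear interpolation at half height (optionally on a trigonometrically
    interpolated spectrum for sub-grid accuracy)."""
    r = spec.data[row].real
    df = abs(spec.axis_hz[1] - spec.axis_hz[0])
    if zoom > 1:
        from nmrkit.processing import _zoom_row

        r = _zoom_row(spec.data[row], zoom).real
        df /= zoom
        if around_index is not None:
            around_index *= zoom
    if around_index is None:
        i = int(np.argmax(r))
    else:
        lo = max(0, around_index - 50 * zoom)
        i = lo + int(np.argmax(r[lo : around_index + 50 * zoom]))
    half = r[i] / 2.0
    left = i
    while left > 0 and r[left] > half:
        left -= 1
    right = i
    while right < r.size - 1 and r[right] > half:
        right += 1
    fl = left + (half - r[left]) / (r[left + 1] - r[left])
    fr = right - (half - r[right]) / (r[right - 1] - r[right])
    return (fr - fl) * df
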