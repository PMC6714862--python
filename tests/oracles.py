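"""Independent reference implementations used as test oracles.

These deliberately use naive O(n²) loops and stay independent of the
package's vectorised/tree-based code paths.
"""

from __future__ import annotations

import struct

import numpy as np


def sampen_bruteforce(x, m: int = 2, r: float | None = None,
                      r_factor: float = 0.2) -> float:
    """Brute-force sample entropy: explicit template-pair counting.

    Counts unordered pairs (i < j) of m- and (m+1)-length templates whose
    Chebyshev distance is <= r, over the first n-m-1 templates of each
    length, and applies the same degenerate-case conventions as the
    package documents (constant -> 0; A=0 -> ln B + ln n; B=0 -> 2 ln n).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    sd = x.std()
    if sd == 0:
        return 0.0
    if r is None:
        r = r_factor * sd

    def count(length: int) -> int:
        n_templates = n - m - 1
        c = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if d <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0:
        return float(2.0 * np.log(n))
    if a == 0:
        return float(np.log(b) + np.log(n))
    return float(-np.log(a / b))


def write_minimal_edf(path, data: np.ndarray, fs: int,
                      channel_names=None) -> None:
    """Write a minimal synthetic EDF file (test fixture only).

    ``data`` is (n_channels, n_samples) in microvolts; samples are stored
    as int16 with a −1000..1000 µV physical range, one-second records.
    This is a deliberately small standalone writer so EDF *reading* can be
    verified against an independently produced file.
    """
    data = np.asarray(data, dtype=np.float64)
    n_ch, n_samp = data.shape
    if n_samp % fs:
        raise ValueError("whole seconds only")
    n_rec = n_samp // fs
    if channel_names is None:
        channel_names = [f"EEG ch{i}" for i in range(n_ch)]
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(s, width):
        s = str(s)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X synthetic", 80), pad("Startdate X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 * (n_ch + 1), 8), pad("", 44), pad(n_rec, 8), pad("1", 8),
        pad(n_ch, 4),
    ])
    per = [
        [pad(name, 16) for name in channel_names],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{phys_min:g}", 8)] * n_ch,
        [pad(f"{phys_max:g}", 8)] * n_ch,
        [pad(dig_min, 8)] * n_ch,
        [pad(dig_max, 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(fs, 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((data - phys_min) * scale + dig_min),
                      dig_min, dig_max).astype(np.int16)
    with open(path, "wb") as f:
        f.write(header)
        for fields in per:
            f.write(b"".join(fields))
        for rec in range(n_rec):
            chunk = digital[:, rec * fs:(rec + 1) * fs]
            for c in range(n_ch):
                f.write(struct.pack(f"<{fs}h", *chunk[c]))
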