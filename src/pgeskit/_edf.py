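"""Minimal EDF (European Data Format) writer.

Writes a single-data-record EDF file with 16-bit samples, one signal per
channel, physical units of microvolts. The physical range per channel is the
symmetric integer range just covering the data, so the quantization step is
(2 * ceil(max |x|)) / 2^16. Reading is done elsewhere through mne, which
parses this layout directly.
"""

from __future__ import annotations

import numpy as np


def write_edf(path, samples_uv: np.ndarray, fs: float, channel_names, patient_id: str = "") -> None:
    """Write ``samples_uv`` (n_channels x n_samples, microvolts) as EDF."""
    samples = np.asarray(samples_uv, dtype=float)
    nch, n = samples.shape
    duration = n / fs
    # symmetric integer physical limits; at least +/-1 uV so flat channels survive
    pmax = [max(1.0, float(np.ceil(np.abs(s).max()))) for s in samples]

    def _field(values, width: int) -> bytes:
        out = b""
        for v in values:
            b = str(v).encode("ascii")
            if len(b) > width:
                raise ValueError(f"EDF header field too long: {v!r}")
            out += b.ljust(width)
        return out

    hdr = b""
    hdr += _field(["0"], 8)                      # version
    hdr += _field([patient_id or "X"], 80)       # patient identification
    hdr += _field(["pgeskit"], 80)               # recording identification
    hdr += _field(["01.01.20"], 8)               # start date dd.mm.yy
    hdr += _field(["00.00.00"], 8)               # start time
    hdr += _field([256 * (nch + 1)], 8)          # header byte count
    hdr += b" " * 44                             # reserved
    hdr += _field([1], 8)                        # number of data records
    hdr += _field([f"{duration:.3f}"], 8)        # record duration, seconds
    hdr += _field([nch], 4)                      # number of signals
    hdr += _field(channel_names, 16)
    hdr += _field([""] * nch, 80)                # transducer
    hdr += _field(["uV"] * nch, 8)               # physical dimension
    hdr += _field([int(-p) for p in pmax], 8)    # physical minimum
    hdr += _field([int(p) for p in pmax], 8)     # physical maximum
    hdr += _field([-32768] * nch, 8)             # digital minimum
    hdr += _field([32767] * nch, 8)              # digital maximum
    hdr += _field([""] * nch, 80)                # prefiltering
    hdr += _field([n] * nch, 8)                  # samples per record
    hdr += _field([""] * nch, 32)                # reserved

    body = b""
    for s, p in zip(samples, pmax):
        scale = (2.0 * p) / 65535.0
        dig = np.round((s + p) / scale).astype(np.int64) - 32768
        body += np.clip(dig, -32768, 32767).astype("<i2").tobytes()

    with open(path, "wb") as f:
        f.write(hdr + body)
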