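import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def write_minimal_edf(path, labels, data, fs):
    """Write a one-record EDF file (synthetic fixture, generated at test
    time).  Physical range equals the digital range, so integer-valued
    samples round-trip exactly through any conforming reader."""
    data = np.asarray(data)
    ns = data.shape[1]
    nch = data.shape[0]
    hdr = b"0" + b" " * 7
    hdr += b" " * 80 + b" " * 80
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 * (nch + 1)).ljust(8).encode()
    hdr += b" " * 44
    hdr += b"1".ljust(8)
    hdr += str(ns / fs).ljust(8).encode()
    hdr += str(nch).ljust(4).encode()

    def f(vals, w):
        return b"".join(str(v).ljust(w).encode() for v in vals)

    hdr += f(labels, 16)
    hdr += f([""] * nch, 80)          # transducer
    hdr += f([""] * nch, 8)           # physical dimension (blank: no rescale)
    hdr += f([-32768] * nch, 8)       # physical min
    hdr += f([32767] * nch, 8)        # physical max
    hdr += f([-32768] * nch, 8)       # digital min
    hdr += f([32767] * nch, 8)        # digital max
    hdr += f([""] * nch, 80)          # prefiltering
    hdr += f([ns] * nch, 8)           # samples per record
    hdr += f([""] * nch, 32)          # reserved
    assert len(hdr) == 256 * (nch + 1)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for ch in range(nch):
            fh.write(data[ch].astype("<i2").tobytes())
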