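"""Shared fixtures: small recordings, fitted models, and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from varconn import MVARModel, Recording, Segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def var1_2ch():
    """A stable 2-channel VAR(1) with unidirectional coupling 1 -> 2."""
    return MVARModel(
        coeffs=np.array([[[0.5, 0.0], [0.3, 0.4]]]),
        noise_cov=np.eye(2),
        fs=250.0,
    )


@pytest.fixture
def var2_3ch():
    """A hand-specified stable 3-channel VAR(2) used for oracle checks."""
    a1 = np.array([
        [0.40, 0.00, 0.15],
        [0.35, 0.30, 0.00],
        [0.00, -0.20, 0.25],
    ])
    a2 = np.array([
        [-0.15, 0.00, 0.00],
        [0.00, 0.10, 0.05],
        [0.20, 0.00, -0.10],
    ])
    noise = np.array([
        [1.0, 0.1, 0.0],
        [0.1, 1.5, 0.0],
        [0.0, 0.0, 0.8],
    ])
    model = MVARModel(coeffs=np.stack([a1, a2]), noise_cov=noise, fs=250.0)
    assert model.is_stable()
    return model


@pytest.fixture
def short_recording(rng):
    data = rng.standard_normal((3, 500))
    return Recording("s01", 0, ["ch0", "ch1", "ch2"], 250.0, data)


def make_segment(model: MVARModel, n_samples: int, seed: int, subject="s00", label=0):
    data = model.simulate(n_samples, seed)
    return Segment(
        subject_id=subject, label=label, segment_index=0, data=data, fs=model.fs,
        channel_names=[f"ch{i}" for i in range(model.m)],
    )


def random_stable_model(rng, m=3, p=2, fs=250.0, scale=0.35):
    """Rejection-sample a random stable MVAR model with diagonal noise."""
    while True:
        coeffs = scale * rng.standard_normal((p, m, m)) / np.sqrt(m * p)
        coeffs[0] += 0.3 * np.eye(m)
        noise = np.diag(rng.uniform(0.5, 2.0, size=m))
        model = MVARModel(coeffs=coeffs, noise_cov=noise, fs=fs)
        if model.is_stable():
            return model


def write_minimal_edf(path: Path, channel_labels, fs, data):
    """Write a minimal single-record EDF file (16-bit, one data record).

    Only what the reader needs: n_channels signals, one record of
    ``n_samples`` points each, physical range chosen to cover the data.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    duration = n_samp / fs
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        s = str(s)
        assert len(s) <= n, s
        return s.ljust(n)

    header = b""
    header += pad("0", 8).encode()
    header += pad("X X X X", 80).encode()          # patient id
    header += pad("Startdate X X X X", 80).encode()  # recording id
    header += pad("01.01.20", 8).encode()
    header += pad("00.00.00", 8).encode()
    header += pad(256 + 256 * n_ch, 8).encode()     # header bytes
    header += pad("", 44).encode()
    header += pad(1, 8).encode()                    # n data records
    header += pad(f"{duration:g}", 8).encode()
    header += pad(n_ch, 4).encode()
    for lab in channel_labels:
        header += pad(lab, 16).encode()
    header += b"".join(pad("", 80).encode() for _ in range(n_ch))   # transducer
    header += b"".join(pad("uV", 8).encode() for _ in range(n_ch))
    header += b"".join(pad(f"{phys_min:g}", 8).encode() for _ in range(n_ch))
    header += b"".join(pad(f"{phys_max:g}", 8).encode() for _ in range(n_ch))
    header += b"".join(pad(dig_min, 8).encode() for _ in range(n_ch))
    header += b"".join(pad(dig_max, 8).encode() for _ in range(n_ch))
    header += b"".join(pad("", 80).encode() for _ in range(n_ch))   # prefilter
    header += b"".join(pad(n_samp, 8).encode() for _ in range(n_ch))
    header += b"".join(pad("", 32).encode() for _ in range(n_ch))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    body = b""
    for ch in range(n_ch):
        digital = np.clip(
            np.round((data[ch] - phys_min) * scale + dig_min), dig_min, dig_max
        ).astype("<i2")
        body += struct.pack(f"<{n_samp}h", *digital.tolist())
    path.write_bytes(header + body)
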