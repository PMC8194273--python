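"""Ground-truth MVAR cohorts with planted directed, band-specific couplings.

Two-class cohorts are generated from known MVAR models so that every
downstream stage — filtering, windowing, MVAR fitting, GPDC/dDTF,
classification and importance ranking — can be validated against a known
answer without any real recordings.

Band localisation uses damped-oscillator AR(2) dynamics: a channel with

    x_t = 2 r cos(2 pi f0 / fs) x_{t-1} - r^2 x_{t-2} + u_t

has a spectral peak at (approximately, exactly as r -> 1) f0 Hz.  When a
planted coupling names a resonance frequency, its *source* channel is
given such dynamics; because GPDC's denominator carries the source's own
lag polynomial |A_jj(f)|, which dips at the resonance, the planted
directed feature then concentrates in the band containing f0.

Subject heterogeneity is multiplicative coefficient jitter — the
simplest mechanism that separates subject-unaware from
leave-subjects-out performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Recording, ValidationError
from .mvar import MVARModel


@dataclass(frozen=True)
class Coupling:
    """One directed lagged coefficient, optionally band-localised.

    ``src``/``dst`` are channel indices; the coefficient is written to
    ``A_lag[dst, src]``.  A self coupling (src == dst) sets the channel's
    own dynamics.  When ``resonance_hz`` is given, the *source* channel's
    self dynamics are replaced by a damped AR(2) resonator at that
    frequency (with the given pole radius ``damping``); for a coupling in
    the class-effect list the resonator is applied in both classes (it is
    scaffolding that band-localises the effect) while the directed
    coefficient itself is present only in class 1.
    """

    src: int
    dst: int
    coeff: float
    lag: int = 1
    resonance_hz: float | None = None
    damping: float = 0.9


def ar2_coefficients(freq: float, damping: float, fs: float) -> tuple[float, float]:
    """Lag-1/lag-2 coefficients of a damped oscillator with poles r e^(+-i theta).

    theta = 2 pi freq / fs; the AR(2) spectrum peaks near ``freq`` for
    pole radius ``damping`` close to 1.
    """
    if not (0 < freq < fs / 2):
        raise ValidationError("resonance frequency must lie in (0, fs/2)")
    if not (0 < damping < 1):
        raise ValidationError("damping (pole radius) must lie in (0, 1)")
    theta = 2 * math.pi * freq / fs
    return 2 * damping * math.cos(theta), -damping * damping


def ar2_unit_variance_noise(a1: float, a2: float) -> float:
    """Innovation variance giving an AR(2) process unit marginal variance.

    Closed form from the Yule-Walker relations:
    var = s2 (1 - a2) / ((1 + a2) ((1 - a2)^2 - a1^2)); solve for s2 at
    var = 1.  Keeping resonant channels at the same power as their
    neighbours mirrors real recordings (channel amplitudes are
    comparable) and avoids the extreme regressor collinearity a raw
    near-unit-root oscillator would inject.
    """
    denom = (1 + a2) * ((1 - a2) ** 2 - a1**2)
    s2 = denom / (1 - a2)
    if not s2 > 0:
        raise ValidationError(f"AR(2) ({a1}, {a2}) is not stationary")
    return s2


@dataclass
class GroundTruthSpec:
    """Generative description of a two-class cohort.

    Defaults describe the toy validation scale: 6 channels at 250 Hz,
    6 + 6 subjects, 3 minutes each, with one theta-band (6 Hz) directed
    coupling 0 -> 1 of strength 0.5 present only in class 1.
    """

    m: int = 6
    fs: float = 250.0
    base_couplings: Sequence[Coupling] | None = None
    class_couplings: Sequence[Coupling] = (
        Coupling(src=0, dst=1, coeff=0.5, resonance_hz=6.0),
    )
    subject_sigma: float = 0.15
    noise_diag: float | Sequence[float] = 1.0
    n_per_class: int = 6
    minutes: float = 3.0
    seed: int = 0
    channel_prefix: str = "ch"
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.base_couplings is None:
            # mild first-order self dynamics on every channel
            self.base_couplings = tuple(
                Coupling(src=i, dst=i, coeff=0.3) for i in range(self.m)
            )

    @property
    def channel_names(self) -> list[str]:
        return [f"{self.channel_prefix}{i}" for i in range(self.m)]

    @property
    def n_samples_per_subject(self) -> int:
        return int(round(self.minutes * 60 * self.fs))


def _required_order(couplings: Sequence[Coupling]) -> int:
    order = 1
    for c in couplings:
        order = max(order, c.lag, 2 if c.resonance_hz is not None else 1)
    return order


def build_subject_model(
    spec: GroundTruthSpec, subject_index: int, class_label: int
) -> MVARModel:
    """Construct one subject's ground-truth model.

    Base couplings (and the resonant scaffolding of class couplings) are
    present in every subject; the directed class-effect coefficients are
    added iff ``class_label == 1``, so for a given subject index the two
    class variants differ in exactly the stated entries.  All non-zero
    coefficients receive seeded per-subject multiplicative jitter
    ``(1 + subject_sigma * z)``, drawn identically for both class
    variants; the jitter is redrawn (up to ``max_retries`` times) until
    the model is stable.
    """
    if class_label not in (0, 1):
        raise ValidationError("class_label must be 0 or 1")
    all_couplings = list(spec.base_couplings) + list(spec.class_couplings)
    p = _required_order(all_couplings)
    m = spec.m
    for c in all_couplings:
        if not (0 <= c.src < m and 0 <= c.dst < m):
            raise ValidationError(f"coupling {c} outside channel range")

    base_noise = np.broadcast_to(np.asarray(spec.noise_diag, float), (m,)).copy()
    ss = np.random.SeedSequence([spec.seed, 7919, subject_index])
    rng = np.random.default_rng(ss)

    def place_resonator(coeffs, noise, c, freq_jitter):
        # Subject variation moves the individual peak frequency (the
        # band-localised analogue of coefficient jitter); the pole radius
        # stays fixed so every draw remains stationary.  The innovation
        # variance is calibrated so the resonant channel keeps unit-scale
        # power like its neighbours.
        freq = float(np.clip(
            c.resonance_hz * freq_jitter,
            0.5 * c.resonance_hz,
            min(1.5 * c.resonance_hz, 0.45 * spec.fs),
        ))
        a1, a2 = ar2_coefficients(freq, c.damping, spec.fs)
        coeffs[0, c.src, c.src] = a1
        coeffs[1, c.src, c.src] = a2
        noise[c.src] = base_noise[c.src] * ar2_unit_variance_noise(a1, a2)

    for attempt in range(spec.max_retries):
        coeffs = np.zeros((p, m, m))
        noise = base_noise.copy()
        for c in spec.base_couplings:
            jitter = 1.0 + spec.subject_sigma * rng.standard_normal()
            if c.resonance_hz is not None:
                place_resonator(coeffs, noise, c, jitter)
                if c.src != c.dst:
                    jitter2 = 1.0 + spec.subject_sigma * rng.standard_normal()
                    coeffs[c.lag - 1, c.dst, c.src] = c.coeff * jitter2
            else:
                coeffs[c.lag - 1, c.dst, c.src] = c.coeff * jitter
        for c in spec.class_couplings:
            # Resonant shaping of the source channel is shared scaffolding
            # present in BOTH classes; only the directed coefficient itself
            # is the class effect, so the two classes differ in exactly the
            # stated entries.
            jitter = 1.0 + spec.subject_sigma * rng.standard_normal()
            jitter2 = 1.0 + spec.subject_sigma * rng.standard_normal()
            if c.resonance_hz is not None:
                place_resonator(coeffs, noise, c, jitter)
            if class_label == 1 and (c.src != c.dst or c.resonance_hz is None):
                coeffs[c.lag - 1, c.dst, c.src] = c.coeff * jitter2
        model = MVARModel(coeffs=coeffs, noise_cov=np.diag(noise), fs=spec.fs)
        if model.is_stable():
            return model
    raise ValidationError(
        f"could not stabilise subject {subject_index} (class {class_label}) "
        f"after {spec.max_retries} jitter redraws"
    )


def subject_models(spec: GroundTruthSpec) -> list[tuple[str, int, MVARModel]]:
    """(subject_id, label, model) for the whole cohort, controls first."""
    out = []
    for label in (0, 1):
        tag = "ctrl" if label == 0 else "pat"
        for i in range(spec.n_per_class):
            out.append((f"{tag}{i:02d}", label, build_subject_model(spec, i, label)))
    return out


def generate_cohort(spec: GroundTruthSpec) -> list[Recording]:
    """Simulate every subject's model; fully reproducible given ``spec.seed``."""
    n = spec.n_samples_per_subject
    recordings = []
    for sid, label, model in subject_models(spec):
        ss = np.random.SeedSequence([spec.seed, 104729, label, int(sid[-2:])])
        data = model.simulate(n, ss)
        recordings.append(
            Recording(sid, label, spec.channel_names, spec.fs, data)
        )
    return recordings


def write_cohort(
    recordings: Sequence[Recording], out_dir: str | Path
) -> Path:
    """Write recordings as CSV plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_recording

    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        write_recording(rec, out_dir / fname)
        rows.append({"subject_id": rec.subject_id, "path": fname, "label": rec.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def null_spec(spec: GroundTruthSpec | None = None, **overrides) -> GroundTruthSpec:
    """A copy of ``spec`` with the class effect removed (label-independent)."""
    spec = spec if spec is not None else GroundTruthSpec()
    return replace(spec, class_couplings=(), **overrides)


def planted_feature_names(spec: GroundTruthSpec) -> list[str]:
    """Feature names (both metrics, the band holding the resonance) of the
    planted class-effect couplings — the ground truth the importance
    ranking should recover."""
    from .connectivity import DEFAULT_BANDS

    names = []
    chans = spec.channel_names
    for c in spec.class_couplings:
        if c.src == c.dst:
            continue
        for band in DEFAULT_BANDS:
            if c.resonance_hz is not None and band.low <= c.resonance_hz <= band.high:
                for metric in ("gpdc", "ddtf"):
                    names.append(f"{metric}/{band.name}/{chans[c.src]}->{chans[c.dst]}")
    return names
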