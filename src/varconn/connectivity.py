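"""Frequency-domain effective-connectivity measures from a fitted MVAR model.

From the lag polynomial of a fitted model, evaluated on a frequency grid,

    A(f) = I - sum_{k=1..p} A_k e^(-i 2 pi f k / fs)
    H(f) = A(f)^-1                      (transfer matrix)
    S(f) = H(f) C H(f)^H                (model spectral matrix)

two directed measures are computed for every ordered channel pair.
Throughout, column j is the *source* and row i is the *sink*:

* GPDC (generalized partial directed coherence), noise-variance weighted
  and column normalised so that sum_i GPDC_ij(f)^2 = 1:

      GPDC_ij(f) = (1/sqrt(C_ii)) |A_ij(f)| /
                   sqrt( sum_k (1/C_kk) |A_kj(f)|^2 )

* dDTF (direct directed transfer function), the product of the
  full-frequency DTF and the partial coherence, which suppresses
  influence mediated through third channels:

      dDTF_ij(f) = eta_ij(f) * chi_ij(f)
      eta_ij(f)^2 = |H_ij(f)|^2 / sum_{f'} sum_k |H_ik(f')|^2
      chi_ij(f)^2 = |P_ij(f)|^2 / (P_ii(f) P_jj(f)),   P = S^-1

Band features are inclusive-endpoint arithmetic means of the measure on a
1 Hz grid; the diagonal is excluded, so a segment with m channels yields
2 metrics x n_bands x m(m-1) named features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import Segment, ValidationError
from .mvar import MVARModel, fit_mvar


class Band(NamedTuple):
    name: str
    low: float
    high: float


#: The five conventional EEG rhythm bands (Hz), inclusive endpoints.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 30.0),
    Band("gamma", 30.0, 50.0),
)

#: Metric evaluation grid: 1..50 Hz in 1 Hz steps (the union of the bands).
DEFAULT_GRID = np.arange(1.0, 51.0, 1.0)

METRICS = ("gpdc", "ddtf")


@dataclass
class SpectralStack:
    """A(f), H(f) and S(f) evaluated on a frequency grid.

    Arrays have shape (n_freqs, m, m), complex.
    """

    freqs: np.ndarray
    A: np.ndarray
    H: np.ndarray
    S: np.ndarray
    fs: float

    @property
    def m(self) -> int:
        return self.A.shape[1]


def spectral_stack(model: MVARModel, freqs: Sequence[float]) -> SpectralStack:
    """Evaluate the frequency-domain matrices of a model on a grid.

    Frequencies must lie strictly inside (0, fs/2).
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= model.fs / 2):
        raise ValidationError(
            f"frequencies must lie in (0, {model.fs / 2:g}) Hz exclusive"
        )
    p, m = model.order, model.m
    # A(f) = I - sum_k A_k e^{-i 2 pi f k / fs}
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / model.fs)  # (F, p)
    A = np.eye(m) - np.einsum("fk,kij->fij", phase, model.coeffs)
    try:
        H = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        bad = [f for f, Af in zip(freqs, A) if abs(np.linalg.det(Af)) < 1e-300]
        raise np.linalg.LinAlgError(
            f"A(f) singular at frequencies {bad} Hz"
        ) from exc
    S = H @ model.noise_cov @ H.conj().transpose(0, 2, 1)
    return SpectralStack(freqs=freqs, A=A, H=H, S=S, fs=model.fs)


def gpdc(stack: SpectralStack, noise_cov: np.ndarray) -> np.ndarray:
    """Generalized partial directed coherence, per frequency.

    Returns a (n_freqs, m, m) non-negative real array with zero diagonal;
    entry (f, i, j) quantifies the direct flow j -> i at frequency f,
    weighted by the innovation variances in ``noise_cov``.
    """
    variances = np.diag(np.asarray(noise_cov, dtype=float))
    if np.any(variances <= 0):
        raise ValidationError("noise covariance diagonal must be strictly positive")
    absA = np.abs(stack.A)  # (F, m, m)
    w = 1.0 / variances  # weight 1/C_kk applied along sink index k
    numer = absA / np.sqrt(variances)[None, :, None]
    denom = np.sqrt(np.einsum("k,fkj->fj", w, absA**2))  # per source column j
    out = numer / denom[:, None, :]
    idx = np.arange(stack.m)
    out[:, idx, idx] = 0.0
    return out


def ddtf(stack: SpectralStack) -> np.ndarray:
    """Direct directed transfer function, per frequency.

    Combines the full-frequency DTF (row-normalised over the *entire*
    evaluation grid of ``stack``) with the partial coherence from the
    inverse spectral matrix; entry (f, i, j) reads channel i as the sink
    of a direct flow from channel j.
    """
    absH2 = np.abs(stack.H) ** 2  # (F, m, m)
    # ffDTF denominator: per sink row i, summed over all freqs and sources
    row_power = absH2.sum(axis=(0, 2))  # (m,)
    eta = np.sqrt(absH2 / row_power[None, :, None])
    try:
        P = np.linalg.inv(stack.S)
    except np.linalg.LinAlgError as exc:
        bad = [f for f, Sf in zip(stack.freqs, stack.S)
               if abs(np.linalg.det(Sf)) < 1e-300]
        raise np.linalg.LinAlgError(f"S(f) singular at frequencies {bad} Hz") from exc
    diag = np.real(np.einsum("fii->fi", P))
    chi = np.abs(P) / np.sqrt(diag[:, :, None] * diag[:, None, :])
    out = eta * chi
    idx = np.arange(stack.m)
    out[:, idx, idx] = 0.0
    return out


def band_average(
    per_freq: np.ndarray,
    freqs: np.ndarray,
    band: Band | tuple[float, float],
    grid_step: float = 1.0,
) -> np.ndarray:
    """Entrywise mean of a per-frequency metric over one band.

    The mean runs over grid points low, low+step, ..., high with both
    endpoints included; the evaluated grid must cover the band.
    """
    low, high = (band.low, band.high) if isinstance(band, Band) else band
    freqs = np.asarray(freqs, dtype=float)
    wanted = np.arange(low, high + grid_step / 2, grid_step)
    sel = []
    for f in wanted:
        hits = np.flatnonzero(np.isclose(freqs, f, atol=1e-9))
        if hits.size == 0:
            raise ValidationError(
                f"band [{low}, {high}] Hz not covered by the evaluated grid"
            )
        sel.append(hits[0])
    return np.asarray(per_freq)[sel].mean(axis=0)


def feature_names(
    channel_names: Sequence[str], bands: Sequence[Band] = DEFAULT_BANDS
) -> list[str]:
    """Canonical feature-name order: metric / band / src->dst, self-pairs excluded."""
    names = []
    for metric in METRICS:
        for band in bands:
            for src in channel_names:
                for dst in channel_names:
                    if src != dst:
                        names.append(f"{metric}/{band.name}/{src}->{dst}")
    return names


def n_features(m: int, n_bands: int = len(DEFAULT_BANDS)) -> int:
    """2 metrics x n_bands x m(m-1) ordered pairs."""
    return 2 * n_bands * m * (m - 1)


@dataclass
class FeatureVector:
    """Named, band-averaged connectivity features of one segment."""

    values: np.ndarray
    names: list[str]
    subject_id: str
    label: int
    segment_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValidationError("values and names must be parallel")


def band_matrices(
    model: MVARModel,
    bands: Sequence[Band] = DEFAULT_BANDS,
    grid: np.ndarray | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Band-averaged GPDC and dDTF matrices of one model.

    Returns ``{metric: {band_name: (m, m) matrix}}`` with column = source.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    stack = spectral_stack(model, grid)
    per_freq = {"gpdc": gpdc(stack, model.noise_cov), "ddtf": ddtf(stack)}
    return {
        metric: {b.name: band_average(vals, grid, b) for b in bands}
        for metric, vals in per_freq.items()
    }


def features_from_model(
    model: MVARModel,
    channel_names: Sequence[str],
    bands: Sequence[Band] = DEFAULT_BANDS,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Flatten band-averaged metrics of a model into the canonical order."""
    mats = band_matrices(model, bands=bands, grid=grid)
    m = model.m
    off = ~np.eye(m, dtype=bool)
    chunks = []
    for metric in METRICS:
        for band in bands:
            # canonical order iterates src (column) outer, dst (row) inner
            chunks.append(mats[metric][band.name].T[off])
    return np.concatenate(chunks), feature_names(channel_names, bands)


def features_from_segment(
    seg: Segment,
    p: int = 5,
    bands: Sequence[Band] = DEFAULT_BANDS,
    grid: np.ndarray | None = None,
) -> FeatureVector:
    """Fit an MVAR and extract the full band-averaged feature vector.

    Deterministic given the segment: fit of order ``p``, spectral stack on
    the 1 Hz union grid (default 1-50 Hz), GPDC and dDTF, band averages,
    all ordered off-diagonal pairs flattened with names
    ``metric/band/src->dst``.
    """
    model = fit_mvar(seg, p)
    values, names = features_from_model(
        model, seg.channel_names or [f"ch{i}" for i in range(seg.n_channels)],
        bands=bands, grid=grid,
    )
    return FeatureVector(
        values=values, names=names,
        subject_id=seg.subject_id, label=seg.label,
        segment_index=seg.segment_index,
    )


@dataclass
class FeatureTable:
    """Feature matrix over segments, with subject and label provenance.

    Rows are segments; columns are the named connectivity features.
    """

    X: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    labels: np.ndarray
    segment_indices: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.segment_indices = np.asarray(self.segment_indices, dtype=int)
        n = self.X.shape[0]
        if not (len(self.subject_ids) == self.labels.size
                == self.segment_indices.size == n):
            raise ValidationError("provenance columns must match the row count")
        if self.X.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names must match the column count")

    @property
    def n_segments(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_segments(
        cls,
        segments: Iterable[Segment],
        p: int = 5,
        bands: Sequence[Band] = DEFAULT_BANDS,
        grid: np.ndarray | None = None,
    ) -> "FeatureTable":
        vectors = [features_from_segment(s, p=p, bands=bands, grid=grid)
                   for s in segments]
        if not vectors:
            raise ValidationError("no segments to build features from")
        names = vectors[0].names
        for v in vectors[1:]:
            if v.names != names:
                raise ValidationError("segments have inconsistent feature spaces")
        return cls(
            X=np.stack([v.values for v in vectors]),
            feature_names=names,
            subject_ids=[v.subject_id for v in vectors],
            labels=np.array([v.label for v in vectors]),
            segment_indices=np.array([v.segment_index for v in vectors]),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame.insert(0, "subject_id", self.subject_ids)
        frame.insert(1, "segment_index", self.segment_indices)
        frame.insert(2, "label", self.labels)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path)
        meta = ["subject_id", "segment_index", "label"]
        names = [c for c in frame.columns if c not in meta]
        return cls(
            X=frame[names].to_numpy(dtype=float),
            feature_names=names,
            subject_ids=[str(s) for s in frame["subject_id"]],
            labels=frame["label"].to_numpy(dtype=int),
            segment_indices=frame["segment_index"].to_numpy(dtype=int),
        )
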