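"""Synthetic two-group curve/scalar/track generators with known truth.

Every downstream stage (quantification, screening, interval testing,
regression) is exercised against data whose differential structure is
chosen up front: per-feature mean shifts that are either invariant across
all windows ("idl"), localized to a window range ("ldl"), or absent
("null"), with AR(1) window autocorrelation and a choice of marginal
shapes.

Each feature draws from its own RNG stream derived from (seed, CRC32 of
the feature name), so adding a feature never perturbs the draws of the
others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import CurveMatrix, ScalarFeatureTable, window_labels

EFFECT_KINDS = ("null", "idl", "ldl")
MARGINALS = ("gaussian", "lognormal", "beta_like")


@dataclass(frozen=True)
class FeatureSpec:
    """One simulated feature.

    ``effect_size`` is the group-1 minus group-2 mean shift; for
    ``effect_kind="ldl"`` it applies only inside ``effect_window_range``
    (1-based inclusive window indices). ``autocorrelation`` is the AR(1)
    coefficient of the latent noise along the window axis.

    The shift is exact in expectation for gaussian and lognormal
    marginals; for ``beta_like`` (content) and integer counts it acts on
    the latent scale and is therefore approximate (documented behaviour).
    """

    name: str
    measure: str = "weighted_average"
    effect_kind: str = "null"
    effect_size: float = 0.0
    effect_window_range: tuple[int, int] | None = None
    marginal: str = "gaussian"
    noise_sd: float = 1.0
    autocorrelation: float = 0.3
    baseline: float | None = None

    def __post_init__(self) -> None:
        if self.measure not in ("content", "count", "weighted_average"):
            raise ValueError(f"{self.name}: unknown measure {self.measure!r}")
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"{self.name}: unknown effect_kind {self.effect_kind!r}")
        if self.marginal not in MARGINALS:
            raise ValueError(f"{self.name}: unknown marginal {self.marginal!r}")
        if self.noise_sd <= 0:
            raise ValueError(f"{self.name}: noise_sd must be > 0")
        if not 0 <= self.autocorrelation < 1:
            raise ValueError(f"{self.name}: autocorrelation must be in [0, 1)")
        if (self.effect_kind == "ldl") != (self.effect_window_range is not None):
            raise ValueError(
                f"{self.name}: effect_window_range is required iff effect_kind='ldl'"
            )

    def default_baseline(self) -> float:
        if self.baseline is not None:
            return self.baseline
        if self.measure == "content":
            return 0.5
        if self.measure == "count":
            return 10.0
        return 0.0


@dataclass(frozen=True)
class SimSpec:
    n_group1: int
    n_group2: int
    n_windows: int = 64
    features: tuple[FeatureSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("both groups need at least 2 regions")
        if self.n_windows < 2 or self.n_windows % 2 != 0:
            raise ValueError("n_windows must be even and >= 2")
        object.__setattr__(self, "features", tuple(self.features))
        for f in self.features:
            if f.effect_window_range is not None:
                lo, hi = f.effect_window_range
                if not (1 <= lo <= hi <= self.n_windows):
                    raise ValueError(
                        f"{f.name}: effect_window_range outside [1, {self.n_windows}]"
                    )


def feature_rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream per feature: adding features leaves others intact."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _ar1_noise(rng: np.random.Generator, n: int, k: int, phi: float, sd: float) -> np.ndarray:
    """Latent gaussian noise, AR(1) along windows with marginal sd ``sd``."""
    z = rng.standard_normal((n, k))
    if phi == 0:
        return sd * z
    e = np.empty_like(z)
    e[:, 0] = z[:, 0]
    scale = np.sqrt(1.0 - phi**2)
    for w in range(1, k):
        e[:, w] = phi * e[:, w - 1] + scale * z[:, w]
    return sd * e


def _shift_profile(f: FeatureSpec, k: int) -> np.ndarray:
    shift = np.zeros(k)
    if f.effect_kind == "idl":
        shift[:] = f.effect_size
    elif f.effect_kind == "ldl":
        lo, hi = f.effect_window_range  # type: ignore[misc]
        shift[lo - 1 : hi] = f.effect_size
    return shift


def _apply_marginal(
    f: FeatureSpec, latent: np.ndarray, mean: np.ndarray
) -> np.ndarray:
    """Map latent AR(1) noise + target mean onto the requested marginal."""
    if f.marginal == "gaussian":
        x = mean + latent
    elif f.marginal == "lognormal":
        # centered lognormal noise: mean preserved exactly, right-skewed
        sd = f.noise_sd
        x = mean + np.exp(latent) - np.exp(sd**2 / 2.0)
    else:  # beta_like: logistic transform of the latent gaussian
        if ((mean <= 0) | (mean >= 1)).any():
            raise ValueError(
                f"{f.name}: beta_like mean (baseline + shift) must stay inside (0, 1)"
            )
        x = 1.0 / (1.0 + np.exp(-(np.log(mean / (1 - mean)) + latent)))
    if f.measure == "content":
        if ((mean < 0) | (mean > 1)).any():
            raise ValueError(f"{f.name}: content mean leaves [0, 1]")
        x = np.clip(x, 0.0, 1.0)
    elif f.measure == "count":
        x = np.maximum(np.round(x), 0.0)
    return x


def simulate_feature(
    f: FeatureSpec, n1: int, n2: int, n_windows: int, seed: int
) -> np.ndarray:
    """(n1 + n2, K) value matrix; group-1 rows first."""
    if f.measure == "content" and f.marginal != "beta_like":
        raise ValueError(f"{f.name}: content features require the beta_like marginal")
    rng = feature_rng(seed, f.name)
    n = n1 + n2
    latent = _ar1_noise(rng, n, n_windows, f.autocorrelation, f.noise_sd)
    mean = np.full((n, n_windows), f.default_baseline())
    mean[:n1] += _shift_profile(f, n_windows)[None, :]
    return _apply_marginal(f, latent, mean)


def simulate_curves(
    spec: SimSpec,
) -> tuple[dict[str, CurveMatrix], np.ndarray]:
    """Simulate every feature of the spec.

    Returns a mapping feature name -> CurveMatrix (group-1 regions first)
    and the shared binary label vector (1 = group 1, 0 = group 2).
    """
    labels = np.concatenate(
        [np.ones(spec.n_group1, int), np.zeros(spec.n_group2, int)]
    )
    region_ids = [f"g1_{i}" for i in range(spec.n_group1)] + [
        f"g2_{i}" for i in range(spec.n_group2)
    ]
    out: dict[str, CurveMatrix] = {}
    for f in spec.features:
        values = simulate_feature(f, spec.n_group1, spec.n_group2, spec.n_windows, spec.seed)
        cm = CurveMatrix(
            feature_name=f.name,
            measure=f.measure,
            values=values,
            region_ids=list(region_ids),
        )
        cm.validate_measure()
        out[f.name] = cm
    return out, labels


def simulate_scalars(
    n1: int,
    n2: int,
    delta: float,
    skew: str = "gaussian",
    seed: int = 0,
    name: str = "scalar",
    sd: float = 1.0,
) -> tuple[ScalarFeatureTable, np.ndarray]:
    """One low-resolution value per region, group means differing by delta.

    ``skew="lognormal"`` produces right-skewed marginals (with the group
    mean difference still exactly delta in expectation), for exercising
    the shifted-log regularization downstream.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 regions")
    if skew not in ("gaussian", "lognormal"):
        raise ValueError(f"unknown skew {skew!r}")
    rng = feature_rng(seed, name)
    n = n1 + n2
    if skew == "gaussian":
        noise = sd * rng.standard_normal(n)
    else:
        noise = np.exp(sd * rng.standard_normal(n)) - np.exp(sd**2 / 2.0)
    values = noise
    values[:n1] += delta
    labels = np.concatenate([np.ones(n1, int), np.zeros(n2, int)])
    ids = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    return ScalarFeatureTable(feature_name=name, values=values, region_ids=ids), labels


# ---------------------------------------------------------------------------
# toy annotation tracks


@dataclass
class TrackBundle:
    """Paths of the generated fixture files plus the intended curve values."""

    elements_bed: Path
    chrom_sizes: Path
    tracks: dict[str, Path]
    intended: dict[str, CurveMatrix]
    labels: np.ndarray


def simulate_tracks(
    spec: SimSpec,
    out_dir: str | Path,
    chrom_length: int | None = None,
    window_bp: int = 1000,
    element_bp: int = 1000,
) -> TrackBundle:
    """Write toy element BED + feature tracks that quantify back exactly.

    Elements are laid head-to-tail on one chromosome with enough spacing
    that flanks never overlap. Content values are quantized to multiples
    of 1/window_bp, counts to integers, so that window quantification of
    the emitted tracks reproduces the intended curves bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves, labels = simulate_curves(spec)
    k = spec.n_windows
    flank_bp = (k // 2) * window_bp
    n = spec.n_group1 + spec.n_group2
    pitch = 2 * flank_bp + element_bp + window_bp  # 1-window gap between flanks
    needed = n * pitch + 2 * flank_bp
    if chrom_length is None:
        chrom_length = needed
    if chrom_length < needed:
        raise ValueError(
            f"chrom_length {chrom_length} too small for {n} elements ({needed} bp needed)"
        )

    chrom = "chrS"
    starts = flank_bp + pitch * np.arange(n)
    region_ids = next(iter(curves.values())).region_ids if curves else [
        f"g1_{i}" for i in range(spec.n_group1)
    ] + [f"g2_{i}" for i in range(spec.n_group2)]

    elements_bed = out_dir / "elements.bed"
    with open(elements_bed, "w") as fh:
        for i, s in enumerate(starts):
            label = "fixed" if labels[i] == 1 else "control"
            fh.write(f"{chrom}\t{s}\t{s + element_bp}\t{region_ids[i]}\t{label}\t+\n")

    chrom_sizes = out_dir / "chrom.sizes"
    chrom_sizes.write_text(f"{chrom}\t{chrom_length}\n")

    tracks: dict[str, Path] = {}
    intended: dict[str, CurveMatrix] = {}
    for fspec in spec.features:
        cm = curves[fspec.name]
        if fspec.measure == "content":
            quantized = np.round(cm.values * window_bp) / window_bp
        elif fspec.measure == "count":
            quantized = np.round(cm.values)
        else:
            quantized = cm.values
        intended[fspec.name] = CurveMatrix(
            feature_name=fspec.name,
            measure=fspec.measure,
            values=quantized,
            region_ids=list(cm.region_ids),
        )
        suffix = "bedgraph" if fspec.measure == "weighted_average" else "bed"
        path = out_dir / f"{fspec.name}.{suffix}"
        with open(path, "w") as fh:
            for i, s in enumerate(starts):
                window_starts = np.concatenate(
                    [
                        s - flank_bp + window_bp * np.arange(k // 2),
                        s + element_bp + window_bp * np.arange(k // 2),
                    ]
                )
                for w, ws in enumerate(window_starts):
                    v = quantized[i, w]
                    if fspec.measure == "content":
                        covered = int(round(v * window_bp))
                        if covered > 0:
                            fh.write(f"{chrom}\t{ws}\t{ws + covered}\n")
                    elif fspec.measure == "count":
                        for j in range(int(v)):
                            # 10-bp motifs spaced inside the window
                            ms = ws + (j * window_bp) // max(int(v), 1)
                            fh.write(f"{chrom}\t{ms}\t{min(ms + 10, ws + window_bp)}\n")
                    else:
                        fh.write(f"{chrom}\t{ws}\t{ws + window_bp}\t{float(v)!r}\n")
        tracks[fspec.name] = path

    return TrackBundle(
        elements_bed=elements_bed,
        chrom_sizes=chrom_sizes,
        tracks=tracks,
        intended=intended,
        labels=labels,
    )
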