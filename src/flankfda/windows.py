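"""Flank construction, element filtering and per-window track quantification.

Coordinates are 0-based half-open (BED convention) throughout. Each element
gets K windows (default 64 x 1 kb): the upstream flank abuts the element
start, the downstream flank abuts the element end, and for minus-strand
elements the window order is inverted so that curves are always oriented in
the element's reading direction.

Element BED files carry the class label in column 5 (the BED score slot):
``chrom  start  end  id  class_label  strand``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import CurveMatrix, ScalarFeatureTable, window_labels

logger = logging.getLogger(__name__)

CLASS_LABELS = ("fixed", "polymorphic", "in_vitro", "control")

DEFAULT_LENGTH_BOUNDS = (60, 11_000)  # bp


@dataclass(frozen=True)
class ElementRecord:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    class_label: str = "fixed"
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.id or self.chrom}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be + or -")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"{self.id}: unknown class label {self.class_label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FlankWindows:
    """Ordered genomic windows around one element, in curve order."""

    element_id: str
    chrom: str
    starts: np.ndarray  # (K,) window starts in curve order
    window_bp: int
    oriented: bool = True
    strand: str = "+"

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_bp

    def span(self) -> tuple[int, int]:
        return int(self.starts.min()), int(self.starts.max()) + self.window_bp


# ---------------------------------------------------------------------------
# file IO


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file; returns at least chrom/start/end columns."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:3])
    df = df.iloc[:, :6]
    df.columns = names[: df.shape[1]]
    _check_intervals(df, path)
    return df


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    _check_intervals(df, path)
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite track values")
    return df


def _check_intervals(df: pd.DataFrame, path: str | Path) -> None:
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValueError(f"{path}: malformed interval at line {bad[0] + 1}")


def read_elements(path: str | Path) -> list[ElementRecord]:
    df = read_bed(path)
    out = []
    for i, row in df.iterrows():
        out.append(
            ElementRecord(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row.get("strand", "+")),
                class_label=str(row.get("score", "fixed")),
                id=str(row.get("name", f"elem{i}")),
            )
        )
    return out


def write_elements(elements: list[ElementRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.id}\t{e.class_label}\t{e.strand}\n"
            )


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals as sorted, disjoint (starts, ends)."""
    if len(starts) == 0:
        return np.empty(0, int), np.empty(0, int)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s), np.asarray(out_e)


def overlap_bp(
    merged_s: np.ndarray, merged_e: np.ndarray, qs: np.ndarray, qe: np.ndarray
) -> np.ndarray:
    """Covered bp of each query window against a merged interval set."""
    qs = np.atleast_1d(qs)
    qe = np.atleast_1d(qe)
    out = np.zeros(len(qs), dtype=int)
    if len(merged_s) == 0:
        return out
    # cumulative covered length up to each merged-interval end
    lengths = merged_e - merged_s
    cum = np.concatenate([[0], np.cumsum(lengths)])

    def covered_before(pos: np.ndarray) -> np.ndarray:
        """Total covered bp in (-inf, pos)."""
        idx = np.searchsorted(merged_e, pos, side="left")
        base = cum[idx]
        partial = np.clip(pos - merged_s[np.minimum(idx, len(merged_s) - 1)], 0, None)
        inside = idx < len(merged_s)
        partial = np.where(inside, np.minimum(partial, lengths[np.minimum(idx, len(merged_s) - 1)]), 0)
        return base + partial

    return (covered_before(qe) - covered_before(qs)).astype(int)


class _TrackIndex:
    """Per-chromosome merged interval sets (with optional values)."""

    def __init__(self, df: pd.DataFrame, merge: bool = True):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy(int)
            e = sub["end"].to_numpy(int)
            if merge:
                s, e = merge_intervals(s, e)
            else:
                order = np.argsort(s, kind="stable")
                s, e = s[order], e[order]
            self.by_chrom[str(chrom)] = (s, e)

    def window_overlap(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        if chrom not in self.by_chrom:
            return np.zeros(len(np.atleast_1d(qs)), dtype=int)
        s, e = self.by_chrom[chrom]
        return overlap_bp(s, e, qs, qe)


# ---------------------------------------------------------------------------
# flank construction and filtering


def build_flanks(
    elements: list[ElementRecord],
    chrom_sizes: dict[str, int],
    flank_kb: int = 32,
    window_kb: int = 1,
    orient: bool = True,
) -> tuple[list[FlankWindows], list[tuple[str, str]]]:
    """K = 2*flank_kb/window_kb windows per element; out-of-bounds dropped.

    Returns the flank list and a drop log of (element_id, reason) pairs.
    """
    if flank_kb % window_kb != 0:
        raise ValueError("window size must divide the flank size")
    flank_bp = flank_kb * 1000
    window_bp = window_kb * 1000
    half = flank_bp // window_bp
    flanks: list[FlankWindows] = []
    dropped: list[tuple[str, str]] = []
    for e in elements:
        size = chrom_sizes.get(e.chrom)
        if size is None:
            dropped.append((e.id, "unknown_chromosome"))
            continue
        if e.start - flank_bp < 0 or e.end + flank_bp > size:
            dropped.append((e.id, "flank_out_of_bounds"))
            logger.info("dropping %s: flank exceeds chromosome bounds", e.id)
            continue
        up = e.start - flank_bp + window_bp * np.arange(half)
        down = e.end + window_bp * np.arange(half)
        starts = np.concatenate([up, down])
        if orient and e.strand == "-":
            starts = starts[::-1].copy()
        flanks.append(
            FlankWindows(
                element_id=e.id,
                chrom=e.chrom,
                starts=starts,
                window_bp=window_bp,
                oriented=orient,
                strand=e.strand,
            )
        )
    return flanks, dropped


@dataclass
class FilterResult:
    retained: list[ElementRecord]
    report: pd.DataFrame  # columns: element_id, rule, detail


def filter_elements(
    elements: list[ElementRecord],
    gap_track: pd.DataFrame | None = None,
    flank_bp: int = 32_000,
    max_gap_frac: float = 0.01,
    max_peer_overlap_bp: int = 1,
    length_bounds: tuple[int, int] | None = DEFAULT_LENGTH_BOUNDS,
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> FilterResult:
    """Apply the exclusion rules; every exclusion is reported with its rule.

    Rules: element length outside bounds; element on an excluded
    chromosome; either flank overlapping assembly gaps by more than
    ``max_gap_frac`` of the flank; the element's flanked span overlapping
    any other retained candidate's span by more than ``max_peer_overlap_bp``
    (both parties excluded).
    """
    rows: list[dict] = []
    candidates: list[ElementRecord] = []
    max_gap_bp = int(max_gap_frac * flank_bp)
    gaps = _TrackIndex(gap_track) if gap_track is not None and len(gap_track) else None
    for e in elements:
        if length_bounds is not None and not (
            length_bounds[0] <= e.length <= length_bounds[1]
        ):
            rows.append({"element_id": e.id, "rule": "length_out_of_bounds",
                         "detail": f"length={e.length}"})
            continue
        if e.chrom in exclude_chroms:
            rows.append({"element_id": e.id, "rule": "excluded_chromosome",
                         "detail": e.chrom})
            continue
        if gaps is not None:
            up = gaps.window_overlap(e.chrom, np.array([e.start - flank_bp]),
                                     np.array([e.start]))[0]
            down = gaps.window_overlap(e.chrom, np.array([e.end]),
                                       np.array([e.end + flank_bp]))[0]
            if max(up, down) > max_gap_bp:
                rows.append({"element_id": e.id, "rule": "gap_overlap",
                             "detail": f"{max(up, down)}bp>{max_gap_bp}bp"})
                continue
        candidates.append(e)

    # pairwise flanked-span overlap: every element involved in an overlap
    # exceeding the threshold is excluded (checked in input order)
    spans = [(e.chrom, e.start - flank_bp, e.end + flank_bp) for e in candidates]
    bad = set()
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if spans[i][0] != spans[j][0]:
                continue
            ov = min(spans[i][2], spans[j][2]) - max(spans[i][1], spans[j][1])
            if ov > max_peer_overlap_bp:
                for idx in (i, j):
                    if idx not in bad:
                        bad.add(idx)
                        rows.append({
                            "element_id": candidates[idx].id,
                            "rule": "flank_overlap",
                            "detail": f"{ov}bp with "
                            f"{candidates[j if idx == i else i].id}",
                        })
    retained = [e for i, e in enumerate(candidates) if i not in bad]
    report = pd.DataFrame(rows, columns=["element_id", "rule", "detail"])
    return FilterResult(retained=retained, report=report)


class PlacementError(RuntimeError):
    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"placed only {achieved}/{requested} control regions before "
            "exhausting rejection-sampling attempts"
        )
        self.requested = requested
        self.achieved = achieved


def make_controls(
    chrom_sizes: dict[str, int],
    ltr_track: pd.DataFrame | None,
    element_flank_spans: list[tuple[str, int, int]],
    n_controls: int,
    max_ltr_fraction: float = 0.02,
    max_flank_fraction: float = 0.01,
    region_bp: int = 64_000,
    seed: int = 0,
    max_attempts_per_control: int = 1000,
) -> list[ElementRecord]:
    """Rejection-sample non-overlapping control regions.

    Each control is a contiguous ``region_bp`` region overlapping the LTR
    track at most ``max_ltr_fraction`` of its length, overlapping element
    flank spans at most ``max_flank_fraction``, and disjoint from
    previously placed controls.
    """
    rng = np.random.default_rng(seed)
    chroms = [c for c, size in chrom_sizes.items() if size >= region_bp]
    if not chroms:
        raise ValueError("no chromosome can hold a control region")
    weights = np.array([chrom_sizes[c] - region_bp + 1 for c in chroms], float)
    weights /= weights.sum()
    ltr = _TrackIndex(ltr_track) if ltr_track is not None and len(ltr_track) else None
    span_df = pd.DataFrame(element_flank_spans, columns=["chrom", "start", "end"])
    spans = _TrackIndex(span_df) if len(span_df) else None

    placed: list[ElementRecord] = []
    placed_by_chrom: dict[str, list[tuple[int, int]]] = {}
    attempts_budget = max_attempts_per_control * n_controls
    attempts = 0
    while len(placed) < n_controls:
        if attempts >= attempts_budget:
            raise PlacementError(n_controls, len(placed))
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, chrom_sizes[chrom] - region_bp + 1))
        end = start + region_bp
        if ltr is not None:
            ov = ltr.window_overlap(chrom, np.array([start]), np.array([end]))[0]
            if ov > max_ltr_fraction * region_bp:
                continue
        if spans is not None:
            ov = spans.window_overlap(chrom, np.array([start]), np.array([end]))[0]
            if ov > max_flank_fraction * region_bp:
                continue
        if any(start < pe and ps < end for ps, pe in placed_by_chrom.get(chrom, [])):
            continue
        placed_by_chrom.setdefault(chrom, []).append((start, end))
        placed.append(
            ElementRecord(
                chrom=chrom,
                start=start,
                end=end,
                strand="+",
                class_label="control",
                id=f"control_{len(placed)}",
            )
        )
    return placed


# ---------------------------------------------------------------------------
# quantification


def quantify_content(track: pd.DataFrame, flanks: list[FlankWindows]) -> CurveMatrix:
    """Fraction of each window covered by the (merged) track intervals."""
    index = _TrackIndex(track, merge=True)
    n = len(flanks)
    k = flanks[0].n_windows if n else 0
    values = np.zeros((n, k))
    for i, fw in enumerate(flanks):
        ov = index.window_overlap(fw.chrom, fw.starts, fw.ends)
        values[i] = ov / fw.window_bp
    return _curve("content", "content", values, flanks)


def quantify_count(track: pd.DataFrame, flanks: list[FlankWindows]) -> CurveMatrix:
    """Number of track records whose start coordinate lies in each window."""
    positions: dict[str, np.ndarray] = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        positions[str(chrom)] = np.sort(sub["start"].to_numpy(int))
    n = len(flanks)
    k = flanks[0].n_windows if n else 0
    values = np.zeros((n, k))
    for i, fw in enumerate(flanks):
        pos = positions.get(fw.chrom)
        if pos is None:
            continue
        values[i] = np.searchsorted(pos, fw.ends) - np.searchsorted(pos, fw.starts)
    return _curve("count", "count", values, flanks)


def quantify_wa(track: pd.DataFrame, flanks: list[FlankWindows]) -> CurveMatrix:
    """bp-weighted average of the track value over each window.

    Windows with no overlapping data are NaN (flagged missing); use
    :func:`impute_missing` before curve-level testing.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy(int), kind="stable")
        by_chrom[str(chrom)] = (
            sub["start"].to_numpy(int)[order],
            sub["end"].to_numpy(int)[order],
            sub["value"].to_numpy(float)[order],
        )
    n = len(flanks)
    k = flanks[0].n_windows if n else 0
    values = np.full((n, k), np.nan)
    for i, fw in enumerate(flanks):
        if fw.chrom not in by_chrom:
            continue
        s, e, v = by_chrom[fw.chrom]
        for w in range(k):
            ws, we = fw.starts[w], fw.starts[w] + fw.window_bp
            # s is sorted; e is not (variable lengths), so mask on e below
            hi = np.searchsorted(s, we, side="left")
            if hi == 0:
                continue
            mask = e[:hi] > ws
            if not mask.any():
                continue
            ov = np.minimum(e[:hi][mask], we) - np.maximum(s[:hi][mask], ws)
            tot = ov.sum()
            if tot > 0:
                values[i, w] = (v[:hi][mask] * ov).sum() / tot
    return _curve("weighted_average", "weighted_average", values, flanks)


def impute_missing(cm: CurveMatrix) -> CurveMatrix:
    """Mean-impute NaN windows from the same region's non-missing windows."""
    values = cm.values.copy()
    for i in range(values.shape[0]):
        row = values[i]
        missing = np.isnan(row)
        if missing.any():
            if missing.all():
                raise ValueError(
                    f"{cm.feature_name}: region {cm.region_ids[i]} has no data"
                )
            row[missing] = row[~missing].mean()
    return CurveMatrix(
        feature_name=cm.feature_name,
        measure=cm.measure,
        values=values,
        region_ids=list(cm.region_ids),
        window_labels=list(cm.window_labels),
    )


def _curve(name: str, measure: str, values: np.ndarray, flanks: list[FlankWindows]) -> CurveMatrix:
    k = values.shape[1]
    return CurveMatrix(
        feature_name=name,
        measure=measure,
        values=values,
        region_ids=[f.element_id for f in flanks],
        window_labels=window_labels(k) if k else [],
    )


def quantify_track(
    track: pd.DataFrame, flanks: list[FlankWindows], measure: str, name: str
) -> CurveMatrix:
    if measure == "content":
        cm = quantify_content(track, flanks)
    elif measure == "count":
        cm = quantify_count(track, flanks)
    elif measure == "weighted_average":
        cm = quantify_wa(track, flanks)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    cm.feature_name = name
    return cm


# ---------------------------------------------------------------------------
# low-resolution scalar features


def quantify_scalar_wa(
    track: pd.DataFrame, flanks: list[FlankWindows], name: str
) -> ScalarFeatureTable:
    """bp-weighted average of a valued track over each whole flanked region."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy(int), kind="stable")
        by_chrom[str(chrom)] = (
            sub["start"].to_numpy(int)[order],
            sub["end"].to_numpy(int)[order],
            sub["value"].to_numpy(float)[order],
        )
    out = np.full(len(flanks), np.nan)
    for i, fw in enumerate(flanks):
        if fw.chrom not in by_chrom:
            continue
        s, e, v = by_chrom[fw.chrom]
        num = 0.0
        den = 0.0
        # accumulate over the windows themselves (excludes the element body)
        for w in range(fw.n_windows):
            ws, we = fw.starts[w], fw.starts[w] + fw.window_bp
            hi = np.searchsorted(s, we, side="left")
            if hi == 0:
                continue
            mask = e[:hi] > ws
            if not mask.any():
                continue
            ov = np.minimum(e[:hi][mask], we) - np.maximum(s[:hi][mask], ws)
            num += (v[:hi][mask] * ov).sum()
            den += ov.sum()
        if den > 0:
            out[i] = num / den
    return ScalarFeatureTable(
        feature_name=name, values=out, region_ids=[f.element_id for f in flanks]
    )


def distance_to_landmarks(
    elements: list[ElementRecord],
    landmarks: dict[str, np.ndarray],
    name: str = "landmark_distance",
) -> ScalarFeatureTable:
    """Distance from each element midpoint to the nearest landmark position.

    ``landmarks`` maps chromosome -> sorted positions (bp). Elements on
    chromosomes without landmarks get NaN.
    """
    out = np.full(len(elements), np.nan)
    for i, e in enumerate(elements):
        pos = landmarks.get(e.chrom)
        if pos is None or len(pos) == 0:
            continue
        out[i] = np.abs(np.asarray(pos) - e.midpoint).min()
    return ScalarFeatureTable(
        feature_name=name, values=out, region_ids=[e.id for e in elements]
    )
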