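"""Domain containers and delimited-text I/O for intensity matrices and EIC tables.

Two kinds of measurement are handled:

* **Integrated intensities** — a ``D × L`` matrix of non-negative ion counts,
  one row per sample, one column per biomolecule (protein, peptide or
  metabolite), carried by :class:`ProfileSet` together with case/control
  labels.  Profiles are normalised to a common total ion count before
  modelling, mirroring standard LC/GC-MS practice.
* **Scan-level EICs** — per sample, one extracted ion chromatogram per
  feature: a fixed-length vector of per-scan ion abundances plus m/z and
  retention-time metadata, carried by :class:`EICPeak` / :class:`EICDataset`.

Missing intensities are distinguished from zeros at parse time: an empty cell
or an ``NA`` token means the feature was not identified in that sample, while
``0`` is a legitimate count.  The consistency filter operates on
identification, not abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileSet",
    "EICPeak",
    "EICDataset",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "filter_consistent_features",
    "normalize_profiles",
    "read_eic_table",
    "write_eic_table",
]

_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


@dataclass
class ProfileSet:
    """A samples × features matrix of non-negative ion intensities.

    Parameters
    ----------
    intensities : ndarray, shape (D, L)
        Ion counts; ``np.nan`` marks a missing (unidentified) entry.
    sample_ids, feature_ids : sequences of str
        Row and column identifiers, unique within their axis.
    group_labels : sequence of str
        Per-sample label, typically ``"case"`` or ``"control"``.
    total_count : float, optional
        Common total ion count after normalisation; ``None`` until
        :func:`normalize_profiles` has been applied.
    """

    intensities: np.ndarray
    sample_ids: List[str]
    feature_ids: List[str]
    group_labels: List[str]
    total_count: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D samples × features matrix")
        d, l = self.intensities.shape
        if len(self.sample_ids) != d:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {d} rows")
        if len(self.feature_ids) != l:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {l} columns")
        if len(self.group_labels) != d:
            raise ValueError("one group label per sample required")
        if len(set(self.sample_ids)) != d:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != l:
            raise ValueError("duplicate feature ids")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValueError("intensities must be non-negative")
        if l and np.all(np.isnan(self.intensities), axis=0).any():
            raise ValueError("a feature column is entirely missing")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_missing(self) -> int:
        """Number of missing (NaN) entries."""
        return int(np.isnan(self.intensities).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=self.sample_ids, columns=self.feature_ids
        )

    def select_samples(self, idx: Sequence[int]) -> "ProfileSet":
        idx = list(idx)
        return ProfileSet(
            self.intensities[idx],
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            [self.group_labels[i] for i in idx],
            self.total_count,
        )


@dataclass
class EICPeak:
    """One extracted ion chromatogram: per-scan abundances for one feature."""

    feature_id: str
    mz: float
    rt_start: float
    scans: np.ndarray  # length-S, non-negative

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans, dtype=float)
        if self.scans.ndim != 1 or self.scans.size < 3:
            raise ValueError("an EIC peak needs at least 3 scans")
        if not np.all(np.isfinite(self.scans)):
            raise ValueError(f"non-finite abundance in feature {self.feature_id!r}")

    @property
    def scan_count(self) -> int:
        return self.scans.size


@dataclass
class EICDataset:
    """Per-sample collections of EIC peaks over a common, ordered feature list."""

    samples: Dict[str, List[EICPeak]]
    group_labels: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("empty EIC dataset")
        ref = self.feature_ids
        for sid, peaks in self.samples.items():
            ids = [p.feature_id for p in peaks]
            if ids != ref:
                raise ValueError(
                    f"sample {sid!r} feature list differs from the common order"
                )
        self._scan_counts()  # raises on per-feature S inconsistency

    def _scan_counts(self) -> List[int]:
        counts: List[int] = []
        for j, fid in enumerate(self.feature_ids):
            ss = {peaks[j].scan_count for peaks in self.samples.values()}
            if len(ss) != 1:
                raise ValueError(f"inconsistent scan count across samples for {fid!r}")
            counts.append(ss.pop())
        return counts

    @property
    def sample_ids(self) -> List[str]:
        return list(self.samples.keys())

    @property
    def feature_ids(self) -> List[str]:
        first = next(iter(self.samples.values()))
        return [p.feature_id for p in first]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def scan_count(self) -> int:
        """Common S when all features share one scan count."""
        counts = set(self._scan_counts())
        if len(counts) != 1:
            raise ValueError("features have differing scan counts")
        return counts.pop()

    def abundance_array(self) -> np.ndarray:
        """Stack scans into a (n_samples, n_features, S) array (common S)."""
        s = self.scan_count
        return np.stack(
            [np.stack([p.scans for p in peaks]) for peaks in self.samples.values()]
        ).reshape(len(self.samples), self.n_features, s)


# ---------------------------------------------------------------------------
# intensity matrix I/O


def _sniff_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_intensity_matrix(
    path: str,
    orientation: str = "samples-in-rows",
    group_labels: Mapping[str, str] | None = None,
    default_label: str = "case",
) -> ProfileSet:
    """Read a delimited intensity matrix into a :class:`ProfileSet`.

    The file has one header row of feature ids and a first column of sample
    ids (or transposed, with ``orientation="samples-in-columns"``).  Empty
    cells and NA tokens are recorded as missing, not zero.
    """
    if orientation not in ("samples-in-rows", "samples-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = [tok.strip() for tok in fh.readline().rstrip("\n").split(sep)]
    if len(set(header[1:])) != len(header[1:]):
        raise ValueError("duplicate column ids in header")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        raise ValueError("duplicate row ids")
    if orientation == "samples-in-columns":
        df = df.T
    body = np.empty(df.shape, dtype=float)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            raw = str(df.iat[i, j]).strip()
            if raw.lower() in _NA_TOKENS:
                body[i, j] = np.nan
                continue
            try:
                body[i, j] = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric value {raw!r} at sample {df.index[i]!r}, "
                    f"feature {df.columns[j]!r}"
                ) from exc
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    if group_labels is None:
        labels = [default_label] * len(sample_ids)
    else:
        labels = [group_labels.get(s, default_label) for s in sample_ids]
    return ProfileSet(body, sample_ids, feature_ids, labels)


def write_intensity_matrix(ps: ProfileSet, path: str, sep: str = ",") -> None:
    """Write a :class:`ProfileSet` body as delimited text (NaN → empty cell)."""
    df = ps.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, na_rep="", float_format="%.17g")


def filter_consistent_features(ps: ProfileSet) -> ProfileSet:
    """Keep only features identified (non-missing) in every sample.

    Column order is preserved; the operation is idempotent.  Raises if no
    feature survives.
    """
    keep = ~np.isnan(ps.intensities).any(axis=0)
    if not keep.any():
        raise ValueError("no feature is consistently identified across samples")
    return ProfileSet(
        ps.intensities[:, keep],
        list(ps.sample_ids),
        [f for f, k in zip(ps.feature_ids, keep) if k],
        list(ps.group_labels),
        ps.total_count,
    )


def normalize_profiles(ps: ProfileSet, target_total: float | None = None) -> ProfileSet:
    """Rescale every sample to a common total ion count.

    By default the target is the mean of the raw row sums, matching the usual
    mean-TIC normalisation of LC/GC-MS profiles.  Missing entries must have
    been filtered first.
    """
    x = ps.intensities
    if np.isnan(x).any():
        raise ValueError("normalize_profiles requires a complete matrix; "
                         "apply filter_consistent_features first")
    row_sums = x.sum(axis=1)
    for sid, s in zip(ps.sample_ids, row_sums):
        if s <= 0:
            raise ValueError(f"sample {sid!r} has zero total ion count")
    if target_total is None:
        target_total = float(row_sums.mean())
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    scaled = x * (target_total / row_sums)[:, None]
    return ProfileSet(
        scaled, list(ps.sample_ids), list(ps.feature_ids), list(ps.group_labels),
        float(target_total),
    )


# ---------------------------------------------------------------------------
# EIC table I/O (long format)

_EIC_COLUMNS = ["sample_id", "feature_id", "mz", "rt_start", "scan_index", "abundance"]


def read_eic_table(
    path: str, group_labels: Mapping[str, str] | None = None,
    default_label: str = "case",
) -> EICDataset:
    """Read a long-format EIC table into an :class:`EICDataset`.

    Required columns: sample_id, feature_id, mz, rt_start, scan_index,
    abundance.  Scan indices must be contiguous 0..S−1 per (sample, feature)
    and S must agree across samples for each feature.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _EIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"EIC table missing columns: {missing}")
    samples: Dict[str, List[EICPeak]] = {}
    feature_order: List[str] | None = None
    for sid, sdf in df.groupby("sample_id", sort=False):
        peaks: List[EICPeak] = []
        for fid, fdf in sdf.groupby("feature_id", sort=False):
            fdf = fdf.sort_values("scan_index")
            idx = fdf["scan_index"].to_numpy(dtype=int)
            s = idx.size
            if not np.array_equal(idx, np.arange(s)):
                raise ValueError(
                    f"scan_index gap for sample {sid!r}, feature {fid!r}: {idx.tolist()}"
                )
            peaks.append(
                EICPeak(
                    feature_id=str(fid),
                    mz=float(fdf["mz"].iloc[0]),
                    rt_start=float(fdf["rt_start"].iloc[0]),
                    scans=fdf["abundance"].to_numpy(dtype=float),
                )
            )
        ids = [p.feature_id for p in peaks]
        if feature_order is None:
            feature_order = ids
        elif set(ids) != set(feature_order):
            raise ValueError(f"sample {str(sid)!r} has a different feature set")
        else:  # impose common order
            pos = {f: i for i, f in enumerate(feature_order)}
            peaks = sorted(peaks, key=lambda p: pos[p.feature_id])
        samples[str(sid)] = peaks
    if group_labels is None:
        labels = {s: default_label for s in samples}
    else:
        labels = {s: group_labels.get(s, default_label) for s in samples}
    ds = EICDataset(samples, labels)
    ds._scan_counts()  # validates per-feature S consistency
    return ds


def write_eic_table(ds: EICDataset, path: str, sep: str = ",") -> None:
    """Write an :class:`EICDataset` in the long delimited format read back by
    :func:`read_eic_table`."""
    rows = []
    for sid, peaks in ds.samples.items():
        for p in peaks:
            for s, a in enumerate(p.scans):
                rows.append((sid, p.feature_id, p.mz, p.rt_start, s, a))
    pd.DataFrame(rows, columns=_EIC_COLUMNS).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )
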