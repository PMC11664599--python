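"""Three-timepoint endpoint assay: min-max normalization and orthogonality.

The endpoint protocol mixes each FAM-labelled peptide with each unlabelled
peptide (1:10 assembled species), reads fluorescence after 1 h and 24 h at
25 C, then anneals (heat, slow-cool) and reads again.  Raw values are put on
a common scale per labelled peptide by min-max normalization against two
annealed anchors:

* minimum = mean annealed fluorescence of the labelled peptide alone in
  buffer (fully quenched);
* maximum = mean annealed fluorescence of the 1:10 homotypic mixture
  (full homotypic exchange).

By construction the annealed buffer controls map to exactly 0 and the
annealed homotypic cells to exactly 1; values are deliberately not clipped
to [0, 1].  The normalized annealed matrix is read for orthogonality: an
off-diagonal (heterotypic) cell at or above a configurable threshold marks
the pair as promiscuous, and a panel is orthogonal when no pair is.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import AnchorError, DegenerateAnchorError, InputError, SchemaError

__all__ = [
    "TIMEPOINTS",
    "BUFFER",
    "PLATE_COLUMNS",
    "PlateRecord",
    "NormalizationAnchors",
    "OrthogonalityReport",
    "PlateNormalizer",
    "validate_plate_records",
    "compute_anchors",
    "minmax_normalize",
    "build_heatmap",
    "classify_orthogonality",
]

log = logging.getLogger(__name__)

TIMEPOINTS = ("1h", "24h", "annealed")
BUFFER = "buffer"
PLATE_COLUMNS = ("labelled_id", "unlabelled_id", "timepoint", "replicate", "fluorescence_au")


@dataclass(frozen=True)
class PlateRecord:
    """One plate-reader measurement in long format."""

    labelled_id: str
    unlabelled_id: str  # peptide name or "buffer" for controls
    timepoint: str
    replicate: int
    fluorescence: float


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        (r.labelled_id, r.unlabelled_id, r.timepoint, r.replicate, r.fluorescence)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(PLATE_COLUMNS))


def validate_plate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a long-format plate table; returns a validated copy."""
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    missing = [c for c in PLATE_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"plate table is missing columns {missing}")
    df = records.loc[:, list(PLATE_COLUMNS)].copy()
    bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise SchemaError(
            f"unknown timepoint labels {bad_tp}; expected one of {list(TIMEPOINTS)}"
        )
    fl = pd.to_numeric(df["fluorescence_au"], errors="coerce")
    bad = df.index[fl.isna()].tolist()
    if bad:
        raise SchemaError(f"non-numeric fluorescence in rows {bad}")
    if (fl < 0).any():
        bad = df.index[fl < 0].tolist()
        raise SchemaError(f"negative fluorescence in rows {bad}")
    df["fluorescence_au"] = fl
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    return df


@dataclass
class NormalizationAnchors:
    """Per-labelled-peptide min/max anchors from annealed records."""

    min_anchor: dict[str, float]
    max_anchor: dict[str, float]
    n_replicates: dict[str, int] = field(default_factory=dict)

    def scale(self, labelled_id: str, raw):
        if labelled_id not in self.min_anchor:
            raise AnchorError(f"no anchors for labelled peptide {labelled_id!r}")
        lo = self.min_anchor[labelled_id]
        hi = self.max_anchor[labelled_id]
        return (raw - lo) / (hi - lo)


def compute_anchors(records: pd.DataFrame) -> NormalizationAnchors:
    """Replicate-mean annealed anchors for every labelled peptide present."""
    df = validate_plate_records(records)
    annealed = df[df["timepoint"] == "annealed"]
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    n_reps: dict[str, int] = {}
    problems = []
    for pep in sorted(df["labelled_id"].unique()):
        ctrl = annealed[
            (annealed["labelled_id"] == pep) & (annealed["unlabelled_id"] == BUFFER)
        ]["fluorescence_au"]
        homo = annealed[
            (annealed["labelled_id"] == pep) & (annealed["unlabelled_id"] == pep)
        ]["fluorescence_au"]
        if ctrl.empty or homo.empty:
            problems.append(pep)
            continue
        if len(ctrl) == 1 or len(homo) == 1:
            log.warning("single-replicate anchor for %s", pep)
        mins[pep] = float(ctrl.mean())
        maxs[pep] = float(homo.mean())
        n_reps[pep] = int(min(len(ctrl), len(homo)))
    if problems:
        raise AnchorError(
            f"missing annealed control and/or homotypic records for {problems}"
        )
    degenerate = [p for p in mins if maxs[p] <= mins[p]]
    if degenerate:
        raise DegenerateAnchorError(
            f"max_anchor <= min_anchor for {degenerate}: no homotypic dequench signal"
        )
    return NormalizationAnchors(min_anchor=mins, max_anchor=maxs, n_replicates=n_reps)


class PlateNormalizer(TransformerMixin, BaseEstimator):
    """Min-max plate normalizer with per-labelled-peptide annealed anchors.

    ``fit`` learns the anchors from the annealed records of the table;
    ``transform`` returns the table with a ``normalized`` column.  The
    fitted anchors live in ``anchors_``.  Use :meth:`matrices` for the
    replicate-averaged (labelled x unlabelled) matrix of each timepoint.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "PlateNormalizer":
        self.anchors_ = compute_anchors(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = validate_plate_records(X)
        unknown = sorted(set(df["labelled_id"]) - set(self.anchors_.min_anchor))
        if unknown:
            raise AnchorError(f"records reference peptides without anchors: {unknown}")
        lo = df["labelled_id"].map(self.anchors_.min_anchor)
        hi = df["labelled_id"].map(self.anchors_.max_anchor)
        df["normalized"] = (df["fluorescence_au"] - lo) / (hi - lo)
        return df

    def matrices(self, X: pd.DataFrame) -> dict[str, pd.DataFrame]:
        """Replicate-mean normalized matrix per timepoint (buffer excluded)."""
        df = self.transform(X)
        df = df[df["unlabelled_id"] != BUFFER]
        out: dict[str, pd.DataFrame] = {}
        for tp in TIMEPOINTS:
            sub = df[df["timepoint"] == tp]
            if sub.empty:
                continue
            out[tp] = sub.pivot_table(
                index="labelled_id", columns="unlabelled_id", values="normalized",
                aggfunc="mean",
            )
        return out


def minmax_normalize(
    records: pd.DataFrame, anchors: NormalizationAnchors | None = None
) -> dict[str, pd.DataFrame]:
    """Normalized (labelled x unlabelled) matrices keyed by timepoint."""
    norm = PlateNormalizer()
    if anchors is None:
        norm.fit(records)
    else:
        norm.anchors_ = anchors
    return norm.matrices(records)


def build_heatmap(
    matrix: pd.DataFrame,
    timepoint: str,
    outdir,
    stem: str | None = None,
) -> tuple[Path, Path]:
    """Write a red-high/blue-low heatmap image and the matrix CSV.

    Rows are labelled peptides, columns unlabelled; missing cells are
    rendered blank.  Returns (image path, csv path).
    """
    if matrix.size == 0:
        raise InputError("empty matrix")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"heatmap_{timepoint}"
    csv_path = outdir / f"{stem}.csv"
    png_path = outdir / f"{stem}.png"
    matrix.to_csv(csv_path)
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        log.warning("matrix for %s has %d missing cells", timepoint, int(np.isnan(values).sum()))
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.6 * matrix.shape[0]))
    cmap = matplotlib.colormaps["coolwarm"].copy()
    cmap.set_bad(color="white")
    vmax = max(1.0, np.nanmax(values)) if np.isfinite(values).any() else 1.0
    im = ax.imshow(np.ma.masked_invalid(values), cmap=cmap, vmin=0.0, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_xlabel("unlabelled peptide")
    ax.set_ylabel("labelled peptide")
    ax.set_title(f"normalized exchange, {timepoint}")
    fig.colorbar(im, ax=ax, label="normalized fluorescence")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return png_path, csv_path


@dataclass
class OrthogonalityReport:
    """Per-pair exchange flags and the panel verdict."""

    threshold: float
    values: dict[tuple[str, str], float]
    flags: dict[tuple[str, str], str]  # "orthogonal" | "promiscuous"
    panel_orthogonal: bool
    diagonal_dominant: bool  # every diagonal beats every off-diagonal in its row/col

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "pairs": [
                {
                    "labelled": l,
                    "unlabelled": u,
                    "normalized_annealed": self.values[(l, u)],
                    "flag": self.flags[(l, u)],
                }
                for (l, u) in sorted(self.values)
            ],
            "panel_orthogonal": self.panel_orthogonal,
            "diagonal_dominant": self.diagonal_dominant,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def classify_orthogonality(
    annealed_matrix: pd.DataFrame, threshold: float = 0.5
) -> OrthogonalityReport:
    """Flag heterotypic pairs with annealed exchange >= threshold.

    Requires a square matrix over a shared peptide panel.  Additionally
    reports diagonal dominance: whether every homotypic (diagonal) value
    exceeds every heterotypic value in its row and its column, the ideal
    pattern of a fully orthogonal set.
    """
    m = annealed_matrix
    if m.shape[0] != m.shape[1] or set(m.index) != set(m.columns):
        raise InputError(
            f"matrix must be square over a shared panel; got rows {list(m.index)} "
            f"vs columns {list(m.columns)}"
        )
    m = m.loc[sorted(m.index), sorted(m.index)]
    values: dict[tuple[str, str], float] = {}
    flags: dict[tuple[str, str], str] = {}
    for i in m.index:
        for j in m.columns:
            v = float(m.at[i, j])
            values[(i, j)] = v
            if i == j:
                flags[(i, j)] = "orthogonal"
            else:
                flags[(i, j)] = "promiscuous" if v >= threshold else "orthogonal"
    panel_ok = all(f == "orthogonal" for f in flags.values())
    diag_dom = True
    for i in m.index:
        d = float(m.at[i, i])
        row_off = [float(m.at[i, j]) for j in m.columns if j != i]
        col_off = [float(m.at[j, i]) for j in m.index if j != i]
        if any(v >= d for v in row_off + col_off):
            diag_dom = False
            break
    return OrthogonalityReport(
        threshold=threshold,
        values=values,
        flags=flags,
        panel_orthogonal=panel_ok,
        diagonal_dominant=diag_dom,
    )
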