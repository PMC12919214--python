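"""Reading, validation, assembly and persistence of observation tables.

The canonical input is a long-format delimited table with header columns
``cell, clone, mutation, vaf, score``: one row per mutation observed in a
cell, carrying that mutation's variant allele frequency and the cell's
disease-relevance score.  A matrix-mode path assembles the same table
from a cell x mutation VAF matrix plus cell->clone and cell->score maps,
replicating each cell's scalar score onto all of its mutation records
(the convention for per-cell phenotypes such as scDRS scores).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .model_core import GroupData

__all__ = [
    "DataFormatError",
    "ValidationError",
    "ReconciliationError",
    "ObservationSet",
    "read_observations",
    "read_table",
    "read_vaf_matrix",
    "assemble_observations",
    "write_posterior",
    "read_chains",
]

REQUIRED_COLUMNS = ("cell", "clone", "mutation", "vaf", "score")

#: group label used for the shared residual variance in summary tables
GLOBAL_GROUP = "_global_"


class DataFormatError(ValueError):
    """The file's structure (columns, dialect) is not as required."""


class ValidationError(ValueError):
    """Row-level content violates an invariant (range, finiteness, duplicates)."""


class ReconciliationError(ValueError):
    """Matrix-mode inputs disagree about which cells exist."""


@dataclass
class ObservationSet:
    """Validated long-format observations, indexed by group.

    A *group* is by default a clone pooled across all cells assigned to it
    (one shared (pi, a, b) per clone); with ``per_cell_groups`` the group
    key becomes the (cell, clone) pair instead.
    """

    table: pd.DataFrame
    group_ids: List[str] = field(init=False)
    _group_cache: Dict[str, GroupData] = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.group_ids = sorted(self.table["group"].unique().tolist())

    # -- construction -------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        per_cell_groups: bool = False,
        validate: bool = True,
        line_offset: int = 2,
    ) -> "ObservationSet":
        """Build from a ``cell,clone,mutation,vaf,score`` frame.

        ``line_offset`` maps frame row 0 to a file line number for error
        messages (2 = header on line 1).
        """
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DataFormatError(f"missing required column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise ValidationError("no observations")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        if validate:
            _validate_rows(df, line_offset)
        df = df.assign(
            vaf=df["vaf"].astype(float),
            score=df["score"].astype(float),
            cell=df["cell"].astype(str),
            clone=df["clone"].astype(str),
            mutation=df["mutation"].astype(str),
        )
        if per_cell_groups:
            df["group"] = df["cell"] + "::" + df["clone"]
        else:
            df["group"] = df["clone"]
        return cls(table=df)

    # -- views ---------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def group_index(self) -> Dict[str, np.ndarray]:
        """Map group id -> integer record positions."""
        return {
            gid: idx.to_numpy()
            for gid, idx in self.table.groupby("group", sort=True).groups.items()
        }

    def group_records(self, group_id: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group_id]

    def group_data(self, group_id: str) -> GroupData:
        """Sampler-ready per-group arrays and sufficient statistics (cached)."""
        if group_id not in self._group_cache:
            sub = self.group_records(group_id)
            if len(sub) == 0:
                raise KeyError(f"unknown group {group_id!r}")
            self._group_cache[group_id] = GroupData.from_records(
                sub["vaf"].to_numpy(), sub["score"].to_numpy()
            )
        return self._group_cache[group_id]

    def group_data_map(self) -> Dict[str, GroupData]:
        return {gid: self.group_data(gid) for gid in self.group_ids}

    def cell_to_group(self) -> Dict[str, str]:
        """First group observed for each cell (unique under default grouping)."""
        return self.table.groupby("cell", sort=True)["group"].first().to_dict()


def _validate_rows(df: pd.DataFrame, line_offset: int) -> None:
    problems: List[str] = []

    vaf = pd.to_numeric(df["vaf"], errors="coerce")
    score = pd.to_numeric(df["score"], errors="coerce")

    bad = vaf.isna() | ~np.isfinite(vaf.fillna(np.nan))
    for i in df.index[bad][:5]:
        problems.append(f"line {i + line_offset}: non-numeric vaf {df['vaf'][i]!r}")
    rng = (~bad) & ((vaf < 0.0) | (vaf > 1.0))
    for i in df.index[rng][:5]:
        problems.append(f"line {i + line_offset}: vaf {vaf[i]} outside [0, 1]")
    bad_s = score.isna() | ~np.isfinite(score.fillna(np.nan))
    for i in df.index[bad_s][:5]:
        problems.append(f"line {i + line_offset}: non-finite score {df['score'][i]!r}")

    dup = df.duplicated(subset=["cell", "clone", "mutation"], keep="first")
    for i in df.index[dup][:5]:
        problems.append(
            f"line {i + line_offset}: duplicate (cell, clone, mutation) triple "
            f"({df['cell'][i]}, {df['clone'][i]}, {df['mutation'][i]})"
        )
    if problems:
        raise ValidationError("; ".join(problems))

    df["vaf"] = vaf
    df["score"] = score


# -- delimited-text helpers -------------------------------------------


def _sep_for(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise DataFormatError(f"unknown table dialect {dialect!r} (expected csv or tsv)")
        return "," if dialect == "csv" else "\t"
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_table(path: str | Path, dialect: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError("no observations") from exc


def read_observations(
    path: str | Path,
    dialect: Optional[str] = None,
    *,
    per_cell_groups: bool = False,
) -> ObservationSet:
    """Read and validate a long-format observation table.

    Dialect (comma vs. tab) is auto-detected from the file extension and
    can be forced with ``dialect`` = ``"csv"`` or ``"tsv"``.  Offending
    rows are reported with their file line numbers, never dropped.
    """
    df = read_table(path, dialect)
    return ObservationSet.from_dataframe(df, per_cell_groups=per_cell_groups)


def read_vaf_matrix(
    path: str | Path,
    *,
    cells: Optional[Sequence[str]] = None,
    mutations: Optional[Sequence[str]] = None,
    dialect: Optional[str] = None,
) -> pd.DataFrame:
    """Read a cell x mutation VAF matrix (cells as rows).

    CSV/TSV matrices carry their own labels (first column = cell ids,
    header = mutation ids).  MatrixMarket (.mtx) files are unlabeled, so
    ``cells`` and ``mutations`` must be supplied.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw, dtype=float)
        if cells is None or mutations is None:
            raise DataFormatError("MTX matrices need explicit cell and mutation labels")
        if mat.shape != (len(cells), len(mutations)):
            raise DataFormatError(
                f"matrix shape {mat.shape} does not match {len(cells)} cells x "
                f"{len(mutations)} mutations"
            )
        return pd.DataFrame(mat, index=list(cells), columns=list(mutations), dtype=float)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    return df.astype(float)


def assemble_observations(
    vaf_matrix: pd.DataFrame,
    clone_map: Mapping[str, str] | pd.Series,
    score_map: Mapping[str, float] | pd.Series,
    *,
    retain_zeros: bool = False,
    per_cell_groups: bool = False,
) -> ObservationSet:
    """Build the long-format table from matrix-mode inputs.

    Emits one record per (cell, mutation) with vaf > 0 (or every entry if
    ``retain_zeros``); the cell's scalar score is replicated onto each of
    its mutation records, and the group label comes from ``clone_map``.
    """
    clone_map = dict(pd.Series(clone_map).astype(str).items())
    score_map = dict(pd.Series(score_map).astype(float).items())

    cells = [str(c) for c in vaf_matrix.index]
    missing_clone = [c for c in cells if c not in clone_map]
    missing_score = [c for c in cells if c not in score_map]
    if missing_clone or missing_score:
        parts = []
        if missing_clone:
            parts.append(f"cells missing from clone map: {', '.join(missing_clone[:10])}")
        if missing_score:
            parts.append(f"cells missing from score map: {', '.join(missing_score[:10])}")
        raise ReconciliationError("; ".join(parts))

    vals = vaf_matrix.to_numpy(dtype=float)
    keep = np.ones_like(vals, dtype=bool) if retain_zeros else vals > 0.0
    rows, cols = np.nonzero(keep)
    if len(rows) == 0:
        raise ValidationError("no observations")
    muts = [str(m) for m in vaf_matrix.columns]
    df = pd.DataFrame(
        {
            "cell": [cells[i] for i in rows],
            "clone": [clone_map[cells[i]] for i in rows],
            "mutation": [muts[j] for j in cols],
            "vaf": vals[rows, cols],
            "score": [score_map[cells[i]] for i in rows],
        }
    )
    return ObservationSet.from_dataframe(df, per_cell_groups=per_cell_groups)


# -- posterior persistence --------------------------------------------

_CHAIN_RE = re.compile(r"chains_(\d+)\.csv$")
# 17 significant digits round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def write_posterior(summary, samples, out_dir: str | Path) -> List[Path]:
    """Persist a fitted run: summary table, thinned chains, run metadata.

    Chains are written with full float precision so a read-back reproduces
    every draw bitwise.  Refuses to write empty samples.
    """
    from .sampler import PosteriorSamples, PosteriorSummary  # local import; avoids cycle

    assert isinstance(samples, PosteriorSamples)
    assert isinstance(summary, PosteriorSummary)
    if samples.n_draws == 0:
        raise ValidationError("refusing to write empty posterior samples")
    if sorted(summary.group_ids) != sorted(samples.group_ids):
        raise ValidationError("summary and samples refer to different groups")

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    written: List[Path] = []

    p = out / "summary.csv"
    summary.table.to_csv(p, index=False, float_format=_FLOAT_FMT)
    written.append(p)

    for c in range(samples.n_chains):
        frame = pd.DataFrame(
            {name: samples.draws[name][c] for name in samples.param_names}
        )
        pc = out / f"chains_{c}.csv"
        frame.to_csv(pc, index=False, float_format=_FLOAT_FMT)
        written.append(pc)

    meta = {
        "seed": samples.config.seed,
        "n_iter": samples.config.n_iter,
        "burn_in": samples.config.burn_in,
        "thin": samples.config.thin,
        "n_chains": samples.config.n_chains,
        "init_mode": samples.config.init_mode,
        "prior": vars(samples.prior).copy(),
        "proposal": {
            "step_a": samples.proposal.step_a,
            "step_b": samples.proposal.step_b,
            "mode_a": samples.proposal.mode_a,
            "adapt": samples.proposal.adapt,
        },
        "group_ids": samples.group_ids,
        "acceptance_rates": samples.acceptance_rates(),
    }
    pm = out / "run_meta.json"
    pm.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(pm)
    return written


def read_chains(out_dir: str | Path) -> tuple[Dict[str, np.ndarray], dict]:
    """Read back chains written by `write_posterior`.

    Returns ``(draws, meta)`` with ``draws[param]`` of shape
    (n_chains, n_draws), bitwise equal to what was written.
    """
    out = Path(out_dir)
    chain_files = sorted(
        (p for p in out.iterdir() if _CHAIN_RE.search(p.name)),
        key=lambda p: int(_CHAIN_RE.search(p.name).group(1)),
    )
    if not chain_files:
        raise DataFormatError(f"no chain files found in {out}")
    frames = [pd.read_csv(p, float_precision="round_trip") for p in chain_files]
    draws = {
        col: np.stack([f[col].to_numpy() for f in frames]) for col in frames[0].columns
    }
    meta_path = out / "run_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return draws, meta
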