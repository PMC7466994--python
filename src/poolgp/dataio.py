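"""Tabular I/O for population allele frequencies and plot-level phenotypes.

The canonical on-disk formats are header-carrying TSV files: a population x
marker frequency matrix (values in [0, 1], ``NA``/empty = missing), a marker
map (marker_id, scaffold, pos_bp with 1-based positions), a panel table
(pop_id, lon, lat, is_cultivar) and a long phenotype table
(pop_id, env, block, trait, value).  Readers validate and reject rather than
coerce; every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKENS = ("NA", "")

PHENOTYPE_COLUMNS = ["pop_id", "env", "block", "trait", "value"]


class FormatError(ValueError):
    """Malformed input table (bad value, duplicate id, missing column)."""


@dataclass
class AlleleFrequencyMatrix:
    """Population x marker alternative-allele frequencies with a marker map.

    Parameters
    ----------
    pop_ids : list of str
        Ordered population labels (rows), unique.
    marker_ids : list of str
        Ordered marker labels (columns), unique.
    values : ndarray of shape (n_pops, n_markers)
        Frequencies in [0, 1]; ``NaN`` marks missing data.
    marker_map : DataFrame
        Indexed by marker id with columns ``scaffold`` and ``pos_bp``
        (1-based position within the scaffold).
    """

    pop_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.pop_ids = [str(p) for p in self.pop_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.pop_ids), len(self.marker_ids)
        if n < 2:
            raise ValueError("need at least 2 populations")
        # p == 0 is tolerated so that an aggressive marker filter can
        # return an empty matrix rather than erroring
        if self.values.shape != (n, p):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {p})")
        if len(set(self.pop_ids)) != n:
            raise FormatError("duplicated population ids")
        if len(set(self.marker_ids)) != p:
            raise FormatError("duplicated marker ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise FormatError("allele frequencies outside [0, 1]")
        missing_map = set(self.marker_ids) - set(map(str, self.marker_map.index))
        if missing_map:
            raise FormatError(f"markers without map entry: {sorted(missing_map)[:5]}")
        self.marker_map = self.marker_map.loc[self.marker_ids, ["scaffold", "pos_bp"]]

    @property
    def n_pops(self) -> int:
        return len(self.pop_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean n x p mask, True where the frequency is missing."""
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pop_ids, columns=self.marker_ids)

    def subset_markers(self, marker_ids: list[str]) -> "AlleleFrequencyMatrix":
        idx = pd.Index(self.marker_ids)
        pos = idx.get_indexer(marker_ids)
        if (pos < 0).any():
            missing = [m for m, q in zip(marker_ids, pos) if q < 0]
            raise KeyError(f"unknown markers: {missing[:5]}")
        return AlleleFrequencyMatrix(
            pop_ids=list(self.pop_ids),
            marker_ids=list(marker_ids),
            values=self.values[:, pos].copy(),
            marker_map=self.marker_map.loc[marker_ids].copy(),
        )

    def subset_pops(self, pop_ids: list[str]) -> "AlleleFrequencyMatrix":
        idx = pd.Index(self.pop_ids)
        pos = idx.get_indexer(pop_ids)
        if (pos < 0).any():
            missing = [p for p, q in zip(pop_ids, pos) if q < 0]
            raise KeyError(f"unknown populations: {missing[:5]}")
        return AlleleFrequencyMatrix(
            pop_ids=list(pop_ids),
            marker_ids=list(self.marker_ids),
            values=self.values[pos, :].copy(),
            marker_map=self.marker_map.copy(),
        )


@dataclass
class PhenotypeRecords:
    """Plot-level phenotype observations in long form.

    One row per (population, environment, block, trait); the combination must
    be unique and values finite.  Feeds the balanced-ANOVA fits.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"phenotype table missing columns {missing_cols}")
        df = df[PHENOTYPE_COLUMNS].copy()
        for c in ("pop_id", "env", "block", "trait"):
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if not np.isfinite(df["value"].to_numpy()).all():
            raise FormatError("non-finite phenotype values")
        dup = df.duplicated(subset=["pop_id", "env", "block", "trait"])
        if dup.any():
            row = df[dup].iloc[0]
            raise FormatError(
                "duplicated record for "
                f"(pop={row.pop_id}, env={row.env}, block={row.block}, trait={row.trait})"
            )
        self.data = df.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def for_trait(self, trait: str, env: str | None = None) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if env is not None:
            sub = sub[sub["env"] == env]
        if sub.empty:
            raise KeyError(f"no records for trait={trait!r}, env={env!r}")
        return sub


def read_frequencies(path: str | Path, map_path: str | Path | None = None) -> AlleleFrequencyMatrix:
    """Read a population x marker frequency TSV (rows = populations).

    The first column holds population ids; remaining columns are markers.
    ``NA`` or empty cells are missing.  A companion marker-map TSV
    (marker_id, scaffold, pos_bp) is read from *map_path*, or from
    ``<path stem>.map.tsv`` next to the matrix; without either, markers are
    placed on a single synthetic scaffold at consecutive positions.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected an id column plus >= 1 marker column")
    pop_col = df.columns[0]
    pop_ids = df[pop_col].tolist()
    marker_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(raw[i, j]).strip()
            if tok in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                v = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {tok!r} at row {pop_ids[i]!r}, column {marker_ids[j]!r}"
                ) from None
            if not 0.0 <= v <= 1.0:
                raise FormatError(
                    f"{path}: frequency {v} outside [0, 1] at row {pop_ids[i]!r}, "
                    f"column {marker_ids[j]!r}"
                )
            values[i, j] = v
    if map_path is None:
        candidate = path.with_suffix("").with_suffix(".map.tsv") if path.suffix else None
        default = path.parent / (path.stem + ".map.tsv")
        map_path = default if default.exists() else (candidate if candidate and candidate.exists() else None)
    if map_path is not None:
        marker_map = read_marker_map(map_path)
    else:
        marker_map = pd.DataFrame(
            {"scaffold": "scaffold_1", "pos_bp": np.arange(1, len(marker_ids) + 1)},
            index=pd.Index(marker_ids, name="marker_id"),
        )
    return AlleleFrequencyMatrix(pop_ids, marker_ids, values, marker_map)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "scaffold": str})
    for col in ("marker_id", "scaffold", "pos_bp"):
        if col not in df.columns:
            raise FormatError(f"{path}: marker map missing column {col!r}")
    if df["marker_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated marker_id in map")
    pos = pd.to_numeric(df["pos_bp"], errors="raise")
    if (pos < 1).any():
        raise FormatError(f"{path}: pos_bp must be 1-based positive")
    out = df.set_index("marker_id")[["scaffold"]].copy()
    out["pos_bp"] = pos.to_numpy(dtype=int)
    return out


def write_frequencies(freqs: AlleleFrequencyMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    """Write the frequency matrix (and its marker map) as TSV, ``NA`` for missing."""
    path = Path(path)
    frame = freqs.to_frame()
    frame.index.name = "pop_id"
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    if map_path is None:
        map_path = path.parent / (path.stem + ".map.tsv")
    mm = freqs.marker_map.copy()
    mm.index.name = "marker_id"
    mm.to_csv(map_path, sep="\t")


def read_phenotypes(path: str | Path) -> PhenotypeRecords:
    """Read a long phenotype TSV with columns pop_id, env, block, trait, value."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    try:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric phenotype value ({exc})") from None
    try:
        return PhenotypeRecords(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_phenotypes(records: PhenotypeRecords, path: str | Path) -> None:
    records.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_panel(panel, path: str | Path) -> None:
    """Write a population panel (pop_id, lon, lat, is_cultivar) as TSV."""
    df = pd.DataFrame(
        {
            "pop_id": panel.pop_ids,
            "lon": panel.lon,
            "lat": panel.lat,
            "is_cultivar": np.asarray(panel.is_cultivar, dtype=int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel(path: str | Path):
    from poolgp.simdata import PopulationPanel

    df = pd.read_csv(path, sep="\t", dtype={"pop_id": str})
    for col in ("pop_id", "lon", "lat"):
        if col not in df.columns:
            raise FormatError(f"{path}: panel missing column {col!r}")
    is_cult = (
        df["is_cultivar"].to_numpy(dtype=bool)
        if "is_cultivar" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    return PopulationPanel(
        pop_ids=df["pop_id"].tolist(),
        lon=df["lon"].to_numpy(dtype=float),
        lat=df["lat"].to_numpy(dtype=float),
        is_cultivar=is_cult,
    )


# ---------------------------------------------------------------------------
# Pipeline configuration

#: Defaults mirror the study's settings: q-value threshold 10%, 100 CV
#: repeats with a 50-population holdout, 500 Mantel permutations, 1000
#: CDmean exchange iterations, constrained-clustering mixing parameter 0.5,
#: MAF > 5% in >= 10 populations.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "maf_min": 0.05,
    "maf_min_pops": 10,
    "q_threshold": 0.10,
    "n_cv_repeats": 100,
    "cv_holdout": 50,
    "n_mantel_perm": 500,
    "cdmean_iters": 1000,
    "clustgeo_alpha": 0.5,
    "calibration_k": 30,
    "gwas_model": "kinship",
    "max_random_markers": 2000,
    "frequencies": None,
    "phenotypes": None,
    "panel": None,
    "clusters": None,
}

_POSITIVE_INT_KEYS = ("n_cv_repeats", "cv_holdout", "n_mantel_perm", "cdmean_iters", "calibration_k", "max_random_markers")


@dataclass
class PipelineConfig:
    """Validated stage parameters for :func:`run_pipeline`."""

    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**DEFAULT_CONFIG, **self.params}
        if not 0.0 <= merged["maf_min"] < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0.0 < merged["q_threshold"] <= 1.0:
            raise ValueError("q_threshold must be in (0, 1]")
        if not 0.0 <= merged["clustgeo_alpha"] <= 1.0:
            raise ValueError("clustgeo_alpha must be in [0, 1]")
        for key in _POSITIVE_INT_KEYS:
            if int(merged[key]) < 1:
                raise ValueError(f"{key} must be a positive integer")
            merged[key] = int(merged[key])
        if merged["gwas_model"] not in ("naive", "structure", "kinship", "structure+kinship"):
            raise ValueError(f"unknown gwas_model {merged['gwas_model']!r}")
        self.params = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(loaded)

    def hash(self) -> str:
        import hashlib
        import json

        blob = json.dumps(self.params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def __getitem__(self, key: str):
        return self.params[key]
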