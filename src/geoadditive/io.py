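"""File-format plumbing: CSV data, GeoJSON geometry, adjacency edge lists,
YAML pipeline configuration, and the row filters applied before analysis."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from .simulate import Geography

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_data_csv",
    "read_geojson",
    "read_centroid_table",
    "read_adjacency",
    "apply_filters",
    "write_classified_geojson",
]

_NA_VALUES = ["", "NA"]


def read_data_csv(path) -> pd.DataFrame:
    """Child-level records: UTF-8 CSV with a header; '' or 'NA' are missing."""
    return pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False,
                       dtype={"region_id": str}, encoding="utf-8")


def read_geojson(path, centroid_table=None) -> Geography:
    """Region geometry from a GeoJSON FeatureCollection.

    Each feature must carry a ``region_id`` property.  Centroids come from
    the optional centroid table, otherwise from polygon representative
    points.
    """
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    ids, polys, cents = [], [], []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        if "region_id" not in props:
            raise ValueError("every feature needs a region_id property")
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        if geom.geom_type != "Polygon":
            raise ValueError(f"unsupported geometry {geom.geom_type}")
        ids.append(str(props["region_id"]))
        polys.append([(float(x), float(y)) for x, y in geom.exterior.coords])
        rp = geom.representative_point()
        cents.append((rp.x, rp.y))
    centroids = np.asarray(cents)
    if centroid_table is not None:
        table = read_centroid_table(centroid_table)
        lut = {r.region_id: (r.longitude, r.latitude)
               for r in table.itertuples()}
        missing = [rid for rid in ids if rid not in lut]
        if missing:
            raise ValueError(f"centroid table lacks regions: {missing}")
        centroids = np.asarray([lut[rid] for rid in ids])
    return Geography(region_ids=ids, centroids=centroids, polygons=polys)


def read_centroid_table(path) -> pd.DataFrame:
    """Delimited text with columns region_id, longitude, latitude (WGS84)."""
    tab = pd.read_csv(path, dtype={"region_id": str})
    need = {"region_id", "longitude", "latitude"}
    if not need <= set(tab.columns):
        raise ValueError(f"centroid table needs columns {sorted(need)}")
    return tab


def read_adjacency(path, region_ids: list[str]) -> np.ndarray:
    """Two-column undirected edge list -> symmetric 0/1 adjacency matrix."""
    pos = {rid: i for i, rid in enumerate(region_ids)}
    A = np.zeros((len(region_ids), len(region_ids)), dtype=int)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()
        if a not in pos or b not in pos:
            raise ValueError(f"edge references unknown region: {line!r}")
        A[pos[a], pos[b]] = A[pos[b], pos[a]] = 1
    np.fill_diagonal(A, 0)
    return A


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (loaded from YAML).

    The outcome is either an existing binary column or a haemoglobin column
    dichotomised at a cutoff (anaemic iff Hb strictly below 11 g/dL by
    default).
    """

    seed: int
    outdir: str
    data_path: str | None = None
    geometry_path: str | None = None
    adjacency_path: str | None = None
    centroid_path: str | None = None
    outcome_column: str | None = "anaemic"
    haemoglobin_column: str | None = None
    haemoglobin_cutoff: float = 11.0
    exclude_regions: list[str] = dataclasses.field(default_factory=list)
    screen_alpha: float = 0.20
    simulate: dict | None = None
    forms: list[str] = dataclasses.field(
        default_factory=lambda: ["M0", "M1", "M2", "M3"])
    model: dict = dataclasses.field(default_factory=dict)
    mcmc: dict = dataclasses.field(
        default_factory=lambda: {"n_iter": 4000, "n_burnin": 1000, "thin": 1})
    raw: dict = dataclasses.field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        paths = raw.get("paths", {})
        outcome = raw.get("outcome", {})
        cutoff = float(outcome.get("cutoff", 11.0))
        if cutoff <= 0:
            raise ValueError("haemoglobin cutoff must be positive")
        cfg = cls(
            seed=int(raw["seed"]),
            outdir=paths.get("outdir", "geoadd_output"),
            data_path=paths.get("data"),
            geometry_path=paths.get("geometry"),
            adjacency_path=paths.get("adjacency"),
            centroid_path=paths.get("centroids"),
            outcome_column=outcome.get("column",
                                       None if "haemoglobin" in outcome
                                       else "anaemic"),
            haemoglobin_column=outcome.get("haemoglobin"),
            haemoglobin_cutoff=cutoff,
            exclude_regions=[str(r) for r in raw.get("exclude_regions", [])],
            screen_alpha=float(raw.get("screen_alpha", 0.20)),
            simulate=raw.get("simulate"),
            forms=list(raw.get("models", {}).get("forms",
                                                 ["M0", "M1", "M2", "M3"])),
            model={k: v for k, v in raw.get("models", {}).items()
                   if k != "forms"},
            mcmc=dict(raw.get("mcmc", {"n_iter": 4000, "n_burnin": 1000,
                                       "thin": 1})),
            raw=raw,
        )
        for p in (cfg.data_path, cfg.geometry_path, cfg.adjacency_path,
                  cfg.centroid_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def apply_filters(data: pd.DataFrame, config: PipelineConfig
                  ) -> tuple[pd.DataFrame, dict]:
    """Apply the study's exclusion rules; return the analytic rows + report.

    Rules: drop rows in excluded regions; derive the binary outcome from
    haemoglobin (anaemic iff Hb < cutoff, strictly) when configured, dropping
    rows with missing haemoglobin; otherwise drop rows with a missing binary
    outcome.
    """
    report = {"n_input": len(data), "excluded_region": 0, "missing_hb": 0,
              "missing_outcome": 0}
    df = data
    if config.exclude_regions:
        drop = df["region_id"].isin(config.exclude_regions)
        report["excluded_region"] = int(drop.sum())
        df = df[~drop]
    if config.haemoglobin_column is not None:
        hb = df[config.haemoglobin_column]
        missing = hb.isna()
        report["missing_hb"] = int(missing.sum())
        df = df[~missing].copy()
        df["anaemic"] = (df[config.haemoglobin_column]
                         < config.haemoglobin_cutoff).astype(int)
    else:
        col = config.outcome_column or "anaemic"
        if col not in df.columns:
            raise ValueError(f"outcome column {col!r} not in data")
        missing = df[col].isna()
        report["missing_outcome"] = int(missing.sum())
        df = df[~missing].copy()
        if col != "anaemic":
            df["anaemic"] = df[col].astype(int)
    report["n_analytic"] = len(df)
    if len(df) == 0:
        raise ValueError("all rows removed by filters; nothing to analyse")
    return df.reset_index(drop=True), report


def write_classified_geojson(geography: Geography,
                             classification: pd.DataFrame, path) -> None:
    """Join the spatial classification back onto the geometry as properties."""
    fc = json.loads(geography.to_geojson())
    rows = classification.set_index("region_id")
    for feat in fc["features"]:
        rid = feat["properties"]["region_id"]
        if rid in rows.index:
            rec = rows.loc[rid]
            for col in classification.columns:
                if col == "region_id":
                    continue
                v = rec[col]
                feat["properties"][col] = (float(v) if isinstance(
                    v, (int, float, np.floating)) else str(v))
    Path(path).write_text(json.dumps(fc, sort_keys=True))
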