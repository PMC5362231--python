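"""Turn opportunistic multi-species record tables into detection histories.

The pipeline mirrors the standard recording-scheme preparation: restrict to
the flight season, drop poorly recorded sites, infer visits (and therefore
non-detections of the target) from records of any species, trim visits to
the target's observed activity months, cap visits per site-year, and attach
list-length and weekly-proportion detection covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import week_of_year

__all__ = [
    "DetectionDataset",
    "filter_sites_by_min_years",
    "restrict_to_flight_season",
    "build_visits",
    "trim_to_target_activity_months",
    "cap_visits",
    "weekly_target_proportion",
    "standardise_covariates",
    "assemble_detection_dataset",
]

REQUIRED_COLUMNS = ("site_id", "date", "species")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table lacks columns: {missing}")
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"])
    return out


@dataclass
class DetectionDataset:
    """Per-year detection histories plus covariates, ready for fitting.

    ``y`` is (S, T_max) with entries 0/1 and NaN padding beyond each site's
    visit count.  ``visit_covariates`` holds matching (S, T_max) arrays.
    ``W`` is the standardised site-covariate matrix (S, M); the
    standardisation constants are kept for predicting at new sites.
    """

    year: int
    site_ids: list
    y: np.ndarray
    visit_covariates: dict = field(default_factory=dict)
    W: np.ndarray | None = None
    occupancy_covariate_names: list = field(default_factory=list)
    standardisation: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def visit_counts(self) -> np.ndarray:
        return (~np.isnan(self.y)).sum(axis=1)

    def save(self, out_dir) -> None:
        """Serialise as CSV matrices plus a JSON metadata file."""
        import json
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.y, index=self.site_ids).to_csv(out / "y.csv", index_label="site_id")
        for name, arr in self.visit_covariates.items():
            pd.DataFrame(arr, index=self.site_ids).to_csv(
                out / f"visit_{name}.csv", index_label="site_id"
            )
        if self.W is not None:
            pd.DataFrame(
                self.W, index=self.site_ids, columns=self.occupancy_covariate_names
            ).to_csv(out / "W.csv", index_label="site_id")
        meta = {
            "year": int(self.year),
            "visit_covariates": list(self.visit_covariates),
            "occupancy_covariate_names": list(self.occupancy_covariate_names),
            "standardisation": self.standardisation,
            "meta": self.meta,
        }
        (out / "dataset.json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, in_dir) -> "DetectionDataset":
        import json
        import pathlib

        src = pathlib.Path(in_dir)
        meta = json.loads((src / "dataset.json").read_text())
        y = pd.read_csv(src / "y.csv", index_col="site_id")
        visit_covs = {
            name: pd.read_csv(src / f"visit_{name}.csv", index_col="site_id").to_numpy()
            for name in meta["visit_covariates"]
        }
        W = None
        if meta["occupancy_covariate_names"]:
            W = pd.read_csv(src / "W.csv", index_col="site_id").to_numpy()
        return cls(
            year=meta["year"],
            site_ids=list(y.index),
            y=y.to_numpy(),
            visit_covariates=visit_covs,
            W=W,
            occupancy_covariate_names=meta["occupancy_covariate_names"],
            standardisation={k: tuple(v) for k, v in meta["standardisation"].items()},
            meta=meta["meta"],
        )

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be 2-D (sites x visits)")
        for name, arr in self.visit_covariates.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.y.shape:
                raise ValueError(f"visit covariate {name!r} shape mismatch")
            self.visit_covariates[name] = arr
        if self.W is not None:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.shape[0] != self.y.shape[0]:
                raise ValueError("W row count must equal number of sites")


def filter_sites_by_min_years(records: pd.DataFrame, min_years: int) -> pd.DataFrame:
    """Keep records at sites recorded (any species) in >= min_years distinct years."""
    if min_years < 1:
        raise ValueError("min_years must be >= 1")
    records = _check_records(records)
    if min_years == 1:
        return records
    years_per_site = (
        records.assign(_year=records["date"].dt.year)
        .groupby("site_id")["_year"]
        .nunique()
    )
    keep = years_per_site.index[years_per_site >= min_years]
    out = records[records["site_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        warnings.warn("min-years site filter removed every record", stacklevel=2)
    return out


def restrict_to_flight_season(
    records: pd.DataFrame, start_month: int = 4, end_month: int = 9
) -> pd.DataFrame:
    """Keep records dated within [start_month, end_month] inclusive."""
    if not 1 <= start_month <= end_month <= 12:
        raise ValueError("require 1 <= start_month <= end_month <= 12")
    records = _check_records(records)
    month = records["date"].dt.month
    return records[(month >= start_month) & (month <= end_month)].reset_index(drop=True)


def build_visits(records: pd.DataFrame, target: str, year: int | None = None) -> pd.DataFrame:
    """One visit per unique (site_id, date) with list length and target flag."""
    records = _check_records(records)
    if year is not None:
        records = records[records["date"].dt.year == year]
    if records.empty:
        raise ValueError("no records to build visits from")
    visits = (
        records.groupby(["site_id", "date"], as_index=False)
        .agg(
            list_length=("species", "nunique"),
            target_detected=("species", lambda s: int((s == target).any())),
        )
        .sort_values(["site_id", "date"], kind="mergesort")
        .reset_index(drop=True)
    )
    visits["month"] = visits["date"].dt.month
    visits["week"] = week_of_year(visits["date"].dt.dayofyear.to_numpy())
    return visits


def trim_to_target_activity_months(visits: pd.DataFrame, target: str | None = None) -> pd.DataFrame:
    """Drop visits outside the first..last month in which the target was seen.

    Raises if the target was never detected (the species/year cannot be
    fitted).  Visits with target detections are retained by construction.
    """
    detected = visits[visits["target_detected"] == 1]
    if detected.empty:
        label = f" for {target!r}" if target else ""
        raise ValueError(f"target species has no records{label}: year cannot be fitted")
    first, last = detected["month"].min(), detected["month"].max()
    keep = (visits["month"] >= first) & (visits["month"] <= last)
    return visits[keep].reset_index(drop=True)


def cap_visits(
    visits: pd.DataFrame, max_visits: int = 50, seed: int | None = None
) -> pd.DataFrame:
    """Cap visits per site, deleting non-detections at random first.

    Site-years with more than ``max_visits`` visits keep every
    target-detection visit; non-detection visits are removed uniformly at
    random (seeded) down to the cap.  If detections alone exceed the cap
    they are all kept (with a warning) — detections are never deleted.
    """
    if max_visits < 1:
        raise ValueError("max_visits must be >= 1")
    rng = np.random.default_rng(seed)
    kept: list[pd.DataFrame] = []
    for site_id, group in visits.groupby("site_id", sort=True):
        if len(group) <= max_visits:
            kept.append(group)
            continue
        det = group[group["target_detected"] == 1]
        non = group[group["target_detected"] == 0]
        n_slots = max_visits - len(det)
        if n_slots < 0:
            warnings.warn(
                f"site {site_id}: {len(det)} detection visits exceed the cap "
                f"of {max_visits}; keeping all detections",
                stacklevel=2,
            )
            kept.append(det)
            continue
        chosen = rng.choice(len(non), size=n_slots, replace=False)
        kept.append(pd.concat([det, non.iloc[np.sort(chosen)]]))
    out = pd.concat(kept).sort_values(["site_id", "date"], kind="mergesort")
    return out.reset_index(drop=True)


def weekly_target_proportion(
    records: pd.DataFrame, target: str, year: int | None = None, mode: str = "share"
) -> pd.Series:
    """Per-week proportion of records that belong to the target species.

    ``mode="share"`` (default): target records / all records within each
    week.  ``mode="distribution"``: each week's share of the target's own
    records over the year.  Weeks with no records map to 0; the index runs
    over weeks 1..53.
    """
    if mode not in ("share", "distribution"):
        raise ValueError("mode must be 'share' or 'distribution'")
    records = _check_records(records)
    if year is not None:
        records = records[records["date"].dt.year == year]
    records = records.drop_duplicates(subset=["site_id", "date", "species"])
    week = pd.Series(
        week_of_year(records["date"].dt.dayofyear.to_numpy()), index=records.index
    )
    is_target = records["species"] == target
    weeks = pd.RangeIndex(1, 54, name="week")
    target_counts = week[is_target].value_counts().reindex(weeks, fill_value=0)
    if mode == "share":
        totals = week.value_counts().reindex(weeks, fill_value=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = target_counts / totals
        return prop.fillna(0.0)
    total_target = target_counts.sum()
    if total_target == 0:
        return pd.Series(0.0, index=weeks)
    return target_counts / total_target


def standardise_covariates(W_raw: pd.DataFrame):
    """Centre and scale each column to mean 0, sample sd 1.

    Returns ``(W, means, sds)``; raises naming the covariate if a column
    has zero variance.
    """
    W_raw = pd.DataFrame(W_raw)
    means = W_raw.mean()
    sds = W_raw.std(ddof=1)
    bad = sds.index[(sds == 0) | ~np.isfinite(sds)]
    if len(bad):
        raise ValueError(f"zero-variance covariate(s): {list(bad)}")
    return (W_raw - means) / sds, means, sds


def assemble_detection_dataset(
    records: pd.DataFrame,
    target: str,
    year: int,
    site_covariates: pd.DataFrame | None = None,
    min_years: int = 3,
    season: tuple[int, int] = (4, 9),
    max_visits: int = 50,
    quadratic: tuple = (),
    log_list_length: bool = True,
    week_proportion_mode: str = "share",
    seed: int | None = None,
) -> DetectionDataset:
    """Run the full preparation pipeline for one target species and year.

    Stage order: season restriction -> min-years site filter -> visit
    building -> activity-month trimming -> visit capping.  Visit
    covariates are (log) list length and the weekly target proportion;
    site covariates are standardised, with optional squared-then-
    restandardised quadratic terms.
    """
    records = _check_records(records)
    counts = {"input": len(records)}
    records = restrict_to_flight_season(records, *season)
    counts["after_season"] = len(records)
    records = filter_sites_by_min_years(records, min_years)
    counts["after_min_years"] = len(records)

    visits = build_visits(records, target, year)
    counts["visits"] = len(visits)
    visits = trim_to_target_activity_months(visits, target)
    counts["visits_after_trim"] = len(visits)
    visits = cap_visits(visits, max_visits, seed=seed)
    counts["visits_after_cap"] = len(visits)

    week_prop = weekly_target_proportion(
        records, target, year, mode=week_proportion_mode
    )

    site_ids = sorted(visits["site_id"].unique())
    t_max = int(visits.groupby("site_id").size().max())
    S = len(site_ids)
    y = np.full((S, t_max), np.nan)
    ll = np.full((S, t_max), np.nan)
    wp = np.full((S, t_max), np.nan)
    site_index = {s: i for i, s in enumerate(site_ids)}
    for site_id, group in visits.groupby("site_id"):
        i = site_index[site_id]
        n = len(group)
        y[i, :n] = group["target_detected"].to_numpy()
        gl = group["list_length"].to_numpy(dtype=float)
        ll[i, :n] = np.log(gl) if log_list_length else gl
        wp[i, :n] = week_prop.reindex(group["week"]).to_numpy()

    ll_name = "log_list_length" if log_list_length else "list_length"
    visit_covs = {ll_name: ll, "week_proportion": wp}

    W = None
    names: list = []
    standardisation: dict = {}
    if site_covariates is not None:
        covs = site_covariates.set_index("site_id") if "site_id" in site_covariates else site_covariates
        missing = [s for s in site_ids if s not in covs.index]
        if missing:
            raise ValueError(f"site covariates missing for sites: {missing[:5]}")
        covs = covs.loc[site_ids]
        W_lin, means, sds = standardise_covariates(covs)
        for c in quadratic:
            if c not in W_lin.columns:
                raise ValueError(f"quadratic term requested for unknown covariate {c!r}")
            sq = W_lin[c] ** 2
            W_lin[f"{c}^2"], m2, s2 = (sq - sq.mean()) / sq.std(ddof=1), sq.mean(), sq.std(ddof=1)
            means[f"{c}^2"], sds[f"{c}^2"] = m2, s2
        W = W_lin.to_numpy()
        names = list(W_lin.columns)
        standardisation = {c: (float(means[c]), float(sds[c])) for c in names}

    return DetectionDataset(
        year=year,
        site_ids=site_ids,
        y=y,
        visit_covariates=visit_covs,
        W=W,
        occupancy_covariate_names=names,
        standardisation=standardisation,
        meta={
            "target": target,
            "filters": {
                "season": season,
                "min_years": min_years,
                "max_visits": max_visits,
                "seed": seed,
            },
            "counts": counts,
        },
    )
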