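"""Tabular readers and writers (tab-delimited, UTF-8, '.' decimal, header row).

Every writer here is paired with a reader that reconstructs the in-memory
object, so pipeline stages can hand results to each other through files and
round-trip tests can assert schema stability.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomics import CogPresenceMatrix
from .growth import DeviationCall, ODTimeSeries, storage_fold_excess

__all__ = [
    "write_plate_tsv",
    "read_plate_tsv",
    "write_cog_tsvs",
    "read_cog_tsvs",
    "write_strain_params_tsv",
    "read_strain_params_tsv",
    "write_calls_tsv",
    "write_trajectory_tsv",
    "write_richness_tsv",
]


def _write(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_plate_tsv(
    series: Sequence[ODTimeSeries], plate_path: str | Path, events_path: str | Path
) -> None:
    """Write curves as long-format TSV plus a companion dilution-event TSV."""
    rows = []
    events = []
    for s in series:
        for t, od, flag in zip(s.time_h, s.od, s.flags):
            rows.append(
                {
                    "time_h": t,
                    "od": od,
                    "strain": s.strain,
                    "replicate": s.replicate,
                    "condition": s.condition,
                    "flag": flag,
                }
            )
        for te, f in s.dilution_events:
            events.append(
                {
                    "time_h": te,
                    "strain": s.strain,
                    "replicate": s.replicate,
                    "condition": s.condition,
                    "dilution_factor": f,
                }
            )
    _write(pd.DataFrame(rows), plate_path)
    _write(
        pd.DataFrame(events, columns=["time_h", "strain", "replicate", "condition", "dilution_factor"]),
        events_path,
    )


def read_plate_tsv(plate_path: str | Path, events_path: str | Path | None = None) -> list[ODTimeSeries]:
    """Rebuild one ODTimeSeries per (strain, replicate, condition) well."""
    plate = pd.read_csv(plate_path, sep="\t", keep_default_na=False, na_values=[])
    plate["flag"] = plate["flag"].astype(str)
    if events_path is not None and Path(events_path).exists():
        events = pd.read_csv(events_path, sep="\t")
    else:
        events = pd.DataFrame(columns=["time_h", "strain", "replicate", "condition", "dilution_factor"])
    out = []
    for (strain, rep, cond), grp in plate.groupby(["strain", "replicate", "condition"], sort=True):
        grp = grp.sort_values("time_h")
        ev = events[
            (events["strain"].astype(str) == str(strain))
            & (events["replicate"].astype(str) == str(rep))
            & (events["condition"].astype(str) == str(cond))
        ].sort_values("time_h")
        out.append(
            ODTimeSeries(
                time_h=grp["time_h"].to_numpy(float),
                od=grp["od"].to_numpy(float),
                strain=str(strain),
                replicate=str(rep),
                condition=str(cond),
                dilution_events=[
                    (float(t), float(f)) for t, f in zip(ev["time_h"], ev["dilution_factor"])
                ],
                flags=grp["flag"].to_numpy(dtype=object),
            )
        )
    return out


def write_cog_tsvs(
    matrix: CogPresenceMatrix,
    presence_path: str | Path,
    labels_path: str | Path,
    pathway_path: str | Path,
) -> None:
    """Presence matrix (0/1), long-format labels, and the pathway map."""
    presence = matrix.presence.astype(int).copy()
    presence.index.name = "strain"
    _write(presence, presence_path, index=True)
    labels = matrix.labels.stack().rename_axis(["strain", "vitamin"]).rename("status")
    _write(labels.reset_index(), labels_path)
    _write(
        pd.DataFrame(sorted(matrix.pathway_map.items()), columns=["cog", "pathway"]),
        pathway_path,
    )


def read_cog_tsvs(
    presence_path: str | Path, labels_path: str | Path, pathway_path: str | Path
) -> CogPresenceMatrix:
    presence = pd.read_csv(presence_path, sep="\t", index_col="strain").astype(bool)
    labels_long = pd.read_csv(labels_path, sep="\t")
    labels = labels_long.pivot(index="strain", columns="vitamin", values="status")
    labels.columns.name = None
    pathway = pd.read_csv(pathway_path, sep="\t")
    return CogPresenceMatrix(
        presence=presence,
        pathway_map=dict(zip(pathway["cog"], pathway["pathway"])),
        labels=labels.reindex(presence.index),
    )


def write_strain_params_tsv(params: pd.DataFrame, path: str | Path) -> None:
    _write(params, path)


def read_strain_params_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "is_auxotroph" in df.columns:
        df["is_auxotroph"] = df["is_auxotroph"].astype(bool)
    return df


def write_calls_tsv(calls: Sequence[DeviationCall], path: str | Path) -> None:
    rows = [
        {
            "strain": c.strain,
            "vitamin": c.vitamin,
            "deviated": c.deviated,
            "deviation_time_h": c.deviation_time_h if c.deviated else np.nan,
            "storage_doublings": c.storage_doublings if c.deviated else np.nan,
            "fold_excess": storage_fold_excess(c.storage_doublings) if c.deviated else np.nan,
        }
        for c in calls
    ]
    _write(
        pd.DataFrame(
            rows,
            columns=[
                "strain",
                "vitamin",
                "deviated",
                "deviation_time_h",
                "storage_doublings",
                "fold_excess",
            ],
        ),
        path,
    )


def write_trajectory_tsv(trajectory, path: str | Path) -> None:
    """Long format: time_h, strain, abundance, glucose_mM, s2_mM."""
    rows = []
    for j, t in enumerate(trajectory.times):
        for strain in trajectory.abundances.index:
            rows.append(
                {
                    "time_h": t,
                    "strain": strain,
                    "abundance": trajectory.abundances.iloc[
                        trajectory.abundances.index.get_loc(strain), j
                    ],
                    "glucose_mM": trajectory.glucose[j],
                    "s2_mM": trajectory.second_carbon[j],
                }
            )
    _write(pd.DataFrame(rows), path)


def write_richness_tsv(series, path: str | Path) -> None:
    """Long format: time_h, group, richness, band_min, band_max."""
    rows = []
    for g in series.richness.columns:
        for t in series.richness.index:
            rows.append(
                {
                    "time_h": t,
                    "group": g,
                    "richness": series.richness.loc[t, g],
                    "band_min": series.band_min.loc[t, g] if series.band_min is not None else np.nan,
                    "band_max": series.band_max.loc[t, g] if series.band_max is not None else np.nan,
                }
            )
    _write(pd.DataFrame(rows), path)
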