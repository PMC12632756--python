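"""Tabular and config I/O for behavior data.

File conventions:

* BoutTable CSV — columns ``trial_id, fly_id, action, start_s, stop_s,
  target_id`` (target may be empty), UTF-8, header required; trial duration
  and optional copulation time travel in a JSON/YAML sidecar or are passed
  explicitly.
* FrameLabelTable CSV — long format ``frame, fly_id, action, value`` with a
  sidecar carrying ``frame_rate`` and ``n_frames``.
* StimSchedule — JSON/YAML document with ``trial_duration_s`` and a
  ``blocks`` list of ``{onset_s, offset_s, frequency_hz, intensity_uw_mm2,
  pulse_width_ms}``.
* Arena geometry — JSON polygons per region, rendered to masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    Bout,
    BoutTable,
    FrameLabelTable,
    StimBlock,
    StimSchedule,
    ValidationError,
)

__all__ = [
    "read_bout_csv",
    "write_bout_csv",
    "read_frame_labels_csv",
    "write_frame_labels_csv",
    "read_stim_schedule",
    "write_stim_schedule",
    "read_geometry_json",
]

BOUT_COLUMNS = ["trial_id", "fly_id", "action", "start_s", "stop_s", "target_id"]


def _load_config(path: Path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def read_bout_csv(
    path,
    trial_duration: float | None = None,
    copulation_time: float | None = None,
    vocabulary: tuple[str, ...] | None = None,
) -> list[BoutTable]:
    """Read one BoutTable per trial_id from a bout CSV.

    When ``trial_duration`` is not given it defaults to the latest bout stop
    per trial (a lower bound; pass the true duration for rate computations).
    """
    df = pd.read_csv(path, dtype={"trial_id": str, "fly_id": str, "target_id": str})
    missing = set(BOUT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValidationError(f"bout CSV missing columns: {sorted(missing)}")
    if "target_id" not in df.columns:
        df["target_id"] = None
    tables = []
    for trial_id, sub in df.groupby("trial_id", sort=True):
        bouts = [
            Bout(
                fly_id=row.fly_id,
                action=row.action,
                start=float(row.start_s),
                stop=float(row.stop_s),
                target_id=None if pd.isna(row.target_id) else str(row.target_id),
            )
            for row in sub.itertuples()
        ]
        dur = trial_duration if trial_duration is not None else max(
            (b.stop for b in bouts), default=0.0
        )
        tables.append(
            BoutTable(
                trial_id=str(trial_id),
                bouts=bouts,
                trial_duration=dur,
                copulation_time=copulation_time,
                vocabulary=vocabulary,
            )
        )
    return tables


def write_bout_csv(tables: list[BoutTable] | BoutTable, path) -> None:
    if isinstance(tables, BoutTable):
        tables = [tables]
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )


def read_frame_labels_csv(path, sidecar) -> FrameLabelTable:
    """Read a long-format frame-label CSV plus its frame_rate/n_frames sidecar."""
    meta = _load_config(Path(sidecar))
    df = pd.read_csv(path, dtype={"fly_id": str, "action": str})
    need = {"frame", "fly_id", "action", "value"}
    if not need <= set(df.columns):
        raise ValidationError(f"frame-label CSV must have columns {sorted(need)}")
    n_frames = int(meta["n_frames"])
    wide = df.pivot_table(
        index="frame", columns=["fly_id", "action"], values="value", fill_value=0
    ).reindex(range(n_frames), fill_value=0)
    wide.columns.names = ["fly_id", "action"]
    return FrameLabelTable(
        trial_id=str(meta.get("trial_id", Path(path).stem)),
        frame_rate=float(meta["frame_rate"]),
        labels=wide.reset_index(drop=True),
    )


def write_frame_labels_csv(table: FrameLabelTable, path, sidecar) -> None:
    long = (
        table.labels.stack(["fly_id", "action"], future_stack=True)
        .rename("value")
        .reset_index()
        .rename(columns={"level_0": "frame"})
    )
    long.columns = ["frame", "fly_id", "action", "value"]
    long = long[long["value"] > 0]  # sparse long format; absent rows are 0
    long.to_csv(path, index=False)
    meta = {
        "trial_id": table.trial_id,
        "frame_rate": table.frame_rate,
        "n_frames": table.n_frames,
    }
    Path(sidecar).write_text(json.dumps(meta, indent=2), encoding="utf-8")


def read_stim_schedule(path) -> StimSchedule:
    doc = _load_config(Path(path))
    blocks = [
        StimBlock(
            onset=float(b["onset_s"]),
            offset=float(b["offset_s"]),
            frequency_hz=float(b.get("frequency_hz", 0.0)),
            intensity_uw_mm2=float(b.get("intensity_uw_mm2", 0.0)),
            pulse_width_ms=float(b.get("pulse_width_ms", 10.0)),
        )
        for b in doc.get("blocks", [])
    ]
    return StimSchedule(blocks=blocks, trial_duration=float(doc["trial_duration_s"]))


def write_stim_schedule(schedule: StimSchedule, path) -> None:
    doc = {
        "trial_duration_s": schedule.trial_duration,
        "blocks": [
            {
                "onset_s": b.onset,
                "offset_s": b.offset,
                "frequency_hz": b.frequency_hz,
                "intensity_uw_mm2": b.intensity_uw_mm2,
                "pulse_width_ms": b.pulse_width_ms,
            }
            for b in schedule.blocks
        ],
    }
    text = (
        yaml.safe_dump(doc, sort_keys=False)
        if str(path).endswith((".yaml", ".yml"))
        else json.dumps(doc, indent=2)
    )
    Path(path).write_text(text, encoding="utf-8")


def read_geometry_json(path, shape: tuple[int, int]):
    """Load arena geometry from JSON polygons {region: [[y, x], ...]}."""
    from skimage.draw import polygon as sk_polygon

    from .placepref import ArenaGeometry

    doc = _load_config(Path(path))
    masks = {}
    for region in ("left", "right", "bowl"):
        mask = np.zeros(shape, dtype=bool)
        if region in doc:
            pts = np.asarray(doc[region], dtype=float)
            rr, cc = sk_polygon(pts[:, 0], pts[:, 1], shape=shape)
            mask[rr, cc] = True
        masks[region] = mask
    return ArenaGeometry(**masks)
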