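"""CSV schemas for raw trial data and the scored-indicator table.

All files are UTF-8 CSVs with a header row and "." decimal separator.
The scored table has one row per participant with the nine indicator
columns, the four paradigm-independent measures, and the covariates;
extra columns round-trip untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .latent import INDICATORS
from .scoring import (
    CategoricalPointingTrial,
    MapPlacementSet,
    PathTrace,
    PointingTrial,
    ProtractorTrial,
)
from .simulate import ParticipantRaw

SCORED_COLUMNS: tuple[str, ...] = INDICATORS + (
    "sbsod",
    "nsq",
    "mrt",
    "ptta",
    "age",
    "gender",
    "kbit_iq",
)

RAW_FILES = (
    "participants.csv",
    "silcton_pointing.csv",
    "squaretown_pointing.csv",
    "temple_pointing.csv",
    "map_placements.csv",
    "squaretown_traces.csv",
    "temple_routes.csv",
    "sbsod_items.csv",
    "nsq_items.csv",
    "mrt_responses.csv",
    "ptta.csv",
)


class SchemaError(ValueError):
    pass


def write_scored_table(table: pd.DataFrame, path) -> None:
    """Write the scored-indicator CSV (floats at full precision)."""
    missing = [c for c in SCORED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"scored table lacks columns: {missing}")
    table.to_csv(path, index=False, float_format="%.17g")


def read_scored_table(path) -> pd.DataFrame:
    """Read a scored-indicator CSV, checking the documented schema."""
    table = pd.read_csv(path)
    missing = [c for c in SCORED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"scored table lacks columns: {missing}")
    return table


# ---------------------------------------------------------------------------
# raw trial-level files


def write_raw_trials(participants: list[ParticipantRaw], outdir) -> None:
    """Write one CSV per task for all participants."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    part, silp, sqp, tmp, maps, traces, legs = [], [], [], [], [], [], []
    sbsod, nsq, mrt, ptta = [], [], [], []
    for p in participants:
        part.append({"id": p.id, "age": p.age, "gender": p.gender, "kbit_iq": p.kbit_iq})
        for t in p.silcton_pointing:
            silp.append(
                {
                    "id": p.id,
                    "station_id": t.station_id,
                    "target_id": t.target_id,
                    "station_route": t.station_route,
                    "target_route": t.target_route,
                    "true_bearing": t.true_bearing,
                    "indicated_bearing": t.indicated_bearing,
                }
            )
        for i, t in enumerate(p.squaretown_pointing):
            sqp.append(
                {"id": p.id, "trial": i, "true_egocentric": t.true_egocentric, "response": t.response}
            )
        for i, t in enumerate(p.temple_pointing):
            tmp.append(
                {
                    "id": p.id,
                    "trial": i,
                    "indicated_angle": t.indicated_angle,
                    "turn_direction": t.turn_direction,
                    "actual_angle": t.actual_angle,
                }
            )
        for paradigm, ms in p.map_placements.items():
            for oid, pxy, txy in zip(ms.object_ids, ms.placed_xy, ms.true_xy):
                maps.append(
                    {
                        "id": p.id,
                        "paradigm": paradigm,
                        "object_id": oid,
                        "x_placed": pxy[0],
                        "y_placed": pxy[1],
                        "x_true": txy[0],
                        "y_true": txy[1],
                    }
                )
        for tr in p.squaretown_traces:
            for k, (x, y) in enumerate(tr.xy):
                traces.append(
                    {
                        "id": p.id,
                        "route_id": tr.route_id,
                        "block": tr.block,
                        "t": k / tr.sample_hz,
                        "x": x,
                        "y": y,
                        "shortest_distance": tr.shortest_distance,
                    }
                )
        for i, (passed, minimum) in enumerate(p.temple_routes):
            legs.append({"id": p.id, "leg": i, "objects_passed": passed, "min_objects": minimum})
        for i, r in enumerate(p.sbsod_items):
            sbsod.append({"id": p.id, "item": i + 1, "response": r})
        for i, c in enumerate(p.nsq_items):
            nsq.append({"id": p.id, "item": i + 1, "category": c})
        for i, (chosen, key) in enumerate(p.mrt_responses):
            mrt.append(
                {
                    "id": p.id,
                    "problem": i + 1,
                    "chosen": ";".join(map(str, chosen)),
                    "key": ";".join(map(str, key)),
                }
            )
        ptta.append(
            {"id": p.id, "points": p.ptta_points, "start_time": p.ptta_start, "end_time": p.ptta_end}
        )
    frames = {
        "participants.csv": part,
        "silcton_pointing.csv": silp,
        "squaretown_pointing.csv": sqp,
        "temple_pointing.csv": tmp,
        "map_placements.csv": maps,
        "squaretown_traces.csv": traces,
        "temple_routes.csv": legs,
        "sbsod_items.csv": sbsod,
        "nsq_items.csv": nsq,
        "mrt_responses.csv": mrt,
        "ptta.csv": ptta,
    }
    for name, rows in frames.items():
        pd.DataFrame(rows).to_csv(outdir / name, index=False, float_format="%.17g")


def read_raw_trials(rawdir) -> list[ParticipantRaw]:
    """Rebuild participant trial structures from the raw CSV directory."""
    rawdir = Path(rawdir)
    for name in RAW_FILES:
        if not (rawdir / name).exists():
            raise SchemaError(f"missing raw file {name}")
    tables = {name: pd.read_csv(rawdir / name) for name in RAW_FILES}
    out = []
    for _, prow in tables["participants.csv"].iterrows():
        pid = prow["id"]

        def rows(name: str) -> pd.DataFrame:
            t = tables[name]
            return t[t["id"] == pid]

        silcton = [
            PointingTrial(
                station_id=r.station_id,
                target_id=r.target_id,
                station_route=r.station_route,
                target_route=r.target_route,
                true_bearing=r.true_bearing,
                indicated_bearing=r.indicated_bearing,
            )
            for r in rows("silcton_pointing.csv").itertuples()
        ]
        sq = [
            CategoricalPointingTrial(int(r.true_egocentric), int(r.response))
            for r in rows("squaretown_pointing.csv").sort_values("trial").itertuples()
        ]
        tt = [
            ProtractorTrial(r.indicated_angle, r.turn_direction, r.actual_angle)
            for r in rows("temple_pointing.csv").sort_values("trial").itertuples()
        ]
        placements = {}
        for paradigm, grp in rows("map_placements.csv").groupby("paradigm"):
            placements[paradigm] = MapPlacementSet(
                object_ids=list(grp["object_id"]),
                placed_xy=grp[["x_placed", "y_placed"]].to_numpy(),
                true_xy=grp[["x_true", "y_true"]].to_numpy(),
            )
        traces = []
        for (route, block), grp in rows("squaretown_traces.csv").groupby(["route_id", "block"]):
            grp = grp.sort_values("t")
            traces.append(
                PathTrace(
                    route_id=route,
                    block=int(block),
                    xy=grp[["x", "y"]].to_numpy(),
                    shortest_distance=float(grp["shortest_distance"].iloc[0]),
                )
            )
        legs = [
            (int(r.objects_passed), int(r.min_objects))
            for r in rows("temple_routes.csv").sort_values("leg").itertuples()
        ]
        mrt_resp = [
            ([int(v) for v in str(r.chosen).split(";") if v != ""], [int(v) for v in str(r.key).split(";")])
            for r in rows("mrt_responses.csv").sort_values("problem").itertuples()
        ]
        pt = rows("ptta.csv").iloc[0]
        out.append(
            ParticipantRaw(
                id=pid,
                age=int(prow["age"]),
                gender=int(prow["gender"]),
                kbit_iq=float(prow["kbit_iq"]),
                latent_true={},
                silcton_pointing=silcton,
                squaretown_pointing=sq,
                temple_pointing=tt,
                map_placements=placements,
                squaretown_traces=traces,
                temple_routes=legs,
                sbsod_items=[int(v) for v in rows("sbsod_items.csv").sort_values("item")["response"]],
                nsq_items=list(rows("nsq_items.csv").sort_values("item")["category"]),
                mrt_responses=mrt_resp,
                ptta_points=int(pt["points"]),
                ptta_start=float(pt["start_time"]),
                ptta_end=float(pt["end_time"]),
            )
        )
    return out


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
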