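"""Reader/writer for the nine-column NONMEM-dialect dataset.

Supported columns: ID TIME DV CMT AMT RATE DUR MDV EVID.  EVID=0 rows are
WBC observations (DV in G/L); EVID=1 rows are infusion events with AMT the
BSA-adjusted dose in mg, DUR the infusion duration in days (0.125 for 3-h
infusions) and RATE=-2 (duration-specified infusion).  TIME is in days and
is re-zeroed to each ID's first record on reading.  This is a dataset
dialect only; no NONMEM control-stream support.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .fitting import CycleData
from .pk import DoseEvent, InfusionSchedule

COLUMNS = ["ID", "TIME", "DV", "CMT", "AMT", "RATE", "DUR", "MDV", "EVID"]

#: CMT indices written by this package: PK central compartment for doses,
#: the circulating-WBC compartment (4 + n_tr with n_tr = 1) for observations
DOSE_CMT = 1
OBS_CMT = 5


class NonmemFormatError(ValueError):
    pass


def _infer_label(events: list[DoseEvent]) -> str:
    """Classify a dosing pattern into a schedule label, else 'custom'."""
    if not events:
        return "custom"
    if len(events) == 1 and events[0].duration >= 4.0:
        daily = events[0].amount / events[0].duration
        for label, per_day in (("C100", 100.0), ("C400", 400.0)):
            if 0.5 <= daily / (per_day * 1.78) <= 2.0:
                return label
        return "custom"
    t0 = min(e.start for e in events)
    days = sorted({int(math.floor(e.start - t0 + 1e-6)) for e in events})
    mean_amt = float(np.mean([e.amount for e in events]))
    intensity = "D" if mean_amt >= 3000.0 else "d"
    pattern = {(0, 2, 4): "135", (0, 1, 2): "123", (0, 1): "12"}.get(tuple(days))
    if pattern is None:
        return "custom"
    label = intensity + pattern
    return label if label in ("D135", "d135", "D123", "D12") else "custom"


def read_nonmem(path) -> list[CycleData]:
    """Parse a NONMEM-dialect CSV into one :class:`CycleData` per ID.

    Malformed rows (unknown EVID, dose rows with RATE != -2 or DUR <= 0,
    observation rows with non-positive DV) raise
    :class:`NonmemFormatError` with the offending row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise NonmemFormatError(f"missing required columns: {missing}")
    cycles = []
    for cid in df["ID"].drop_duplicates():
        sub = df[df["ID"] == cid]
        t0 = float(sub["TIME"].min())
        if np.isnan(t0):
            raise NonmemFormatError(f"ID {cid}: missing TIME values")
        events, times, dv = [], [], []
        for row in sub.itertuples():
            rowno = row.Index + 2  # header + 1-based
            evid = int(row.EVID)
            t = float(row.TIME) - t0
            if t < -1e-9:
                raise NonmemFormatError(f"row {rowno}: negative relative TIME")
            if evid == 1:
                if not float(row.AMT) > 0:
                    raise NonmemFormatError(f"row {rowno}: dose row with AMT <= 0")
                if int(row.RATE) != -2:
                    raise NonmemFormatError(f"row {rowno}: dose row RATE must be -2")
                if not float(row.DUR) > 0:
                    raise NonmemFormatError(f"row {rowno}: dose row DUR must be > 0")
                events.append(DoseEvent(start=t, duration=float(row.DUR),
                                        amount=float(row.AMT)))
            elif evid == 0:
                if not float(row.DV) > 0:
                    raise NonmemFormatError(f"row {rowno}: observation with DV <= 0")
                times.append(t)
                dv.append(float(row.DV))
            else:
                raise NonmemFormatError(f"row {rowno}: EVID must be 0 or 1, got {evid}")
        schedule = InfusionSchedule(tuple(events), bsa=1.78, label=_infer_label(events))
        cycles.append(CycleData(cycle_id=str(cid), times=np.array(times),
                                wbc=np.array(dv), schedule=schedule,
                                label=schedule.label))
    return cycles


def write_nonmem(cycles, path) -> None:
    """Inverse of :func:`read_nonmem` on the supported dialect.

    Records are ordered by time within each ID, observations before doses at
    equal times; write -> read -> write is idempotent.
    """
    rows = []
    for cycle in cycles:
        recs = [(t, 0, {"ID": cycle.cycle_id, "TIME": t, "DV": w, "CMT": OBS_CMT,
                        "AMT": 0.0, "RATE": 0, "DUR": 0.0, "MDV": 0, "EVID": 0})
                for t, w in zip(cycle.times, cycle.wbc)]
        recs += [(e.start, 1, {"ID": cycle.cycle_id, "TIME": e.start, "DV": 0.0,
                               "CMT": DOSE_CMT, "AMT": e.amount, "RATE": -2,
                               "DUR": e.duration, "MDV": 1, "EVID": 1})
                 for e in cycle.schedule.events]
        recs.sort(key=lambda r: (r[0], r[1]))
        rows.extend(r[2] for r in recs)
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def group_by_patient(cycles) -> dict[str, list[CycleData]]:
    """Group cycles by their patient id (falling back to the cycle id)."""
    out: dict[str, list[CycleData]] = {}
    for c in cycles:
        out.setdefault(c.patient_id or c.cycle_id, []).append(c)
    return out


def split_cycles(cycle: CycleData, gap_days: float = 14.0) -> list[CycleData]:
    """Split a patientwise record into consolidation cycles at dosing gaps.

    A new cycle starts at each dose event separated from the previous dosing
    block by more than ``gap_days``; observations are attached to the cycle
    whose dosing block precedes them and each cycle's clock is re-zeroed to
    its first record.
    """
    events = sorted(cycle.schedule.events, key=lambda e: e.start)
    if not events:
        return [cycle]
    blocks = [[events[0]]]
    for e in events[1:]:
        if e.start - blocks[-1][-1].end > gap_days:
            blocks.append([])
        blocks[-1].append(e)
    # cycle boundaries: midpoint rule is fragile; use the first dose of the
    # next block as the cut so late-recovery samples stay with their cycle
    cuts = [b[0].start for b in blocks[1:]] + [math.inf]
    out = []
    prev_cut = -math.inf
    for i, block in enumerate(blocks):
        m = (cycle.times >= prev_cut) & (cycle.times < cuts[i])
        t_sel, w_sel = cycle.times[m], cycle.wbc[m]
        t0 = min(block[0].start, t_sel[0] if t_sel.size else block[0].start)
        sched = InfusionSchedule(
            tuple(DoseEvent(e.start - t0, e.duration, e.amount) for e in block),
            bsa=cycle.schedule.bsa, label=_infer_label(block))
        out.append(CycleData(cycle_id=f"{cycle.cycle_id}C{i + 1}", times=t_sel - t0,
                             wbc=w_sel, schedule=sched, label=sched.label,
                             patient_id=cycle.patient_id or cycle.cycle_id))
        prev_cut = cuts[i]
    return out
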