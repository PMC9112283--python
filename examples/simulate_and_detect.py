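"""Simulate one hair-cell neuromast and quantify its spontaneous events.

Builds the day-3 hair-cell preset (10 cells, 15 min at 3 s volumes),
runs the erosion-baseline ΔF/F0 pipeline and event detection, and prints
the per-neuromast summary statistics.
"""
import pandas as pd

from nmspont.events import AnalysisConfig, detect_events, summarize
from nmspont.synthetic import build_preset, generate_traces
from nmspont.traces import trace_from_raw

model = build_preset("hair_cell_day3", seed=1)
bundle = generate_traces(model)

cfg = AnalysisConfig()  # threshold 0.10 dF/F0, prominence 0.10
dffs, tables = {}, []
for (cell_id, comp), sim in bundle.traces.items():
    if comp != "soma":  # quantify the cytosolic signal
        continue
    trace = trace_from_raw(sim.F, model.frame_interval_s, window_frames=41)
    key = (model.neuromast_id, cell_id, comp)
    dffs[key] = trace.dff
    tables.append(detect_events(trace.dff, cfg, model.frame_interval_s, key))

events = pd.concat(tables, ignore_index=True)
per_roi, per_nm = summarize(events, dffs, model.recording_s)

print(f"{len(events)} events detected across {len(dffs)} hair cells")
print(per_nm.round(4).to_string(index=False))
print(
    "\nmean_duration_s is the grand mean above-threshold event width; the "
    "preset's ground-truth duration is 14.22 s.  average_magnitude is the "
    "mean thresholded dF/F0 per frame over the 900 s recording."
)
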