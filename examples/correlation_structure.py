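"""Supporting-cell population coupling, with and without gap junctions.

Supporting cells are electrically coupled through gap junctions and show
strongly synchronized spontaneous calcium activity (neighbor Pearson
R ~ 0.5); blocking gap junctions with flufenamic acid (FFA) decouples
them (R ~ 0.08).  Both states are simulated at matched seeds and the
neighbor-averaged correlation recovered by the pipeline.
"""
from nmspont.correlation import neighbor_mean_r
from nmspont.synthetic import build_preset, generate_traces
from nmspont.traces import trace_from_raw

for condition in (None, "FFA"):
    model = build_preset("supporting_day3", seed=11, condition=condition)
    bundle = generate_traces(model)
    dffs = {
        cell_id: trace_from_raw(sim.F, model.frame_interval_s, 41).dff
        for (cell_id, _comp), sim in bundle.traces.items()
    }
    positions = {c.cell_id: c.position_um for c in model.cells}
    _per_cell, mean_r = neighbor_mean_r(dffs, positions, k=3)
    label = condition or "control"
    print(f"{label:>8}: neighbor-averaged Pearson R = {mean_r:.3f}")

print(
    "\nEach cell is correlated against its 3 nearest neighbors and the "
    "values averaged per neuromast; ground-truth coupling is 0.50 "
    "(control) vs 0.08 (FFA)."
)
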