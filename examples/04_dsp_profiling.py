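"""Digital spatial profiling: QC, normalisation, differential proteins.

Simulates a GeoMx-style immune-panel experiment (3 regions x 2
compartments per patient), gates AOIs on scan QC, normalises to the
positive controls and the IgG background, and compares the lymph-node
stroma against the superficial primary.
"""

from spatial_ith import dsp_profiling as dsp
from spatial_ith.synthetic_data import DSPConfig, simulate_dsp

result = simulate_dsp(DSPConfig(seed=42))
records = dsp.read_aoi_table_from_frame(result.aoi_frame)
passed, report = dsp.qc_filter(records)
print(
    f"QC: {report.n_passed}/{report.n_input} AOIs pass "
    f"(FOV fails {report.n_fail_fov}, binding-density fails "
    f"{report.n_fail_binding_density}, nuclei/area fails {report.n_fail_nuclei_area})"
)

panel = result.panel
normed = dsp.control_normalize(passed, panel)
signal = dsp.background_normalize(normed, panel)

stroma = {
    region: [
        a.aoi_id for a in passed if a.region == region and a.compartment == "stroma"
    ]
    for region in ("LN_met", "PT_sup")
}
table = dsp.differential_proteins(
    signal.loc[stroma["LN_met"]], signal.loc[stroma["PT_sup"]]
)
sig = table[table.significant].sort_values("fdr")
print(f"\nLN_met vs PT_sup, stromal compartment ({len(table)} proteins tested):")
for protein, row in sig.iterrows():
    direction = "up" if row.log2_fc > 0 else "down"
    print(
        f"  {protein}: log2FC = {row.log2_fc:+.2f} ({direction} in LN_met), "
        f"FDR = {row.fdr:.2e}"
    )
print("planted effects were CD8 x2, CD20 x2, SMA x0.5 in LN_met stroma")

scores = dsp.cell_abundance(signal, panel)
meta = {a.aoi_id: a for a in passed}
for cell in ("B cells", "CD8 T cells"):
    ln = scores.loc[stroma["LN_met"], cell].mean()
    pt = scores.loc[stroma["PT_sup"], cell].mean()
    print(
        f"\n{cell} abundance score (mean log2 marker signal): "
        f"LN_met {ln:.2f} vs PT_sup {pt:.2f}"
    )
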