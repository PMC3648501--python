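"""Simulate the combined Notch-Wnt clock and summarize its oscillation.

Builds the reference-calibrated combined model, integrates 1200 minutes of
the limit cycle under a constant extracellular Wnt signal, and prints the
period, amplitude and phase class of every target-gene mRNA.  Expected
output: all five genes cycling with a period near 120 minutes; Lfng, Hes7
and Nkd1 mutually in phase; Axin2 and Dll1 in antiphase with them.
"""

from somiteclock import (
    SimulationConfig,
    build_combined_model,
    integrate,
    measure,
    phase_relation,
)

model = build_combined_model()  # shipped reference parameters + initial state
traj = integrate(model, SimulationConfig(t_end=1200.0))

print(f"{'gene':8s} {'species':16s} {'period':>8s} {'amplitude':>10s}  phase vs Lfng")
for gene, species in model.readouts.items():
    s = measure(traj, species)
    if gene == "Lfng":
        phase = "-"
    else:
        phase = phase_relation(traj, "Lfng_mRNA_cyt", species).classification.value
    print(f"{gene:8s} {species:16s} {s.period:8.1f} {s.amplitude:10.2f}  {phase}")

traj.to_csv("combined_trajectory.csv")
print("\nfull trajectory written to combined_trajectory.csv")
print("periods are in minutes; amplitudes are peak-to-trough in arbitrary "
      "concentration units")
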