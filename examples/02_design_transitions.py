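"""Build an MRM transition list and check scheduled-acquisition load.

Takes two peptides, enumerates their highest-ranked y/b transitions with
carbamidomethyl-fixed masses, and reports the concurrency profile of a
scheduled run with 2-minute retention windows.
"""

from isomrm.assay import (AssayPeptide, enumerate_transitions, schedule,
                          transitions_to_frame)

peptides = [
    AssayPeptide("AAFDDAIAELDTLSEESYK", group_label="HSPA8-like",
                 retention_time=12.4),
    AssayPeptide("LLQDFFNGK", group_label="HSPA1-like",
                 retention_time=13.1),
]

transitions = []
for pep in peptides:
    transitions.extend(enumerate_transitions(pep, n_transitions=6))

print(transitions_to_frame(transitions).to_string(index=False))

report = schedule(transitions, cycle_time=1.5, min_dwell=0.05)
print(f"\nmax concurrency: {report.max_concurrency} transitions")
print(f"dwell-time violations: {report.n_violations} grid points")
print("\nEach row is one Q1/Q3 pair; product_mz is the fragment m/z with "
      "fixed cysteine carbamidomethylation. Overlapping retention windows "
      "share the duty cycle, so concurrency bounds the dwell per transition.")
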