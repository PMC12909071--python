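"""Apply the Arg-count/charge activity rule to the designed-peptide panel.

Quadruplex unfolding by Arg-rich peptides needs at least 13 arginines and
a net positive charge: (RQ)10 falls short on Arg, (RE)20 is charge-
neutralized by its glutamates, and the rest of the panel is active.
"""

from quadrufold.peptides import panel_summary, predict_unfolding, profile_peptide

PANEL = ["(RQ)10", "(RQ)15", "(RQ)20", "(RGG)13", "(RP)15", "(RP)20",
         "(RE)20", "R30"]

profiles = [profile_peptide(s, s) for s in PANEL]
calls = [predict_unfolding(p) for p in profiles]
df = panel_summary(profiles, calls)
print(df[["id", "arg_count", "net_charge", "active", "reasons"]].to_string(index=False))
print(f"\nminimum Arg count among active peptides: {df.attrs['min_active_arg']}")
# 13 — set by (RGG)13; within the RQ series the threshold is 15 repeats
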