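"""Recompute salt-stress effect sizes from the published treatment means.

Loads the packaged photosynthetic and metabolite tables and prints the
percent change of the salt-stressed group (S) against the control (CK), and
of the best lanthanum dose (S+La0.75) against S. Positive "decrease" values
mean salt stress lowered the indicator; positive "increase" values mean the
lanthanum treatment raised it again.
"""

from saltlax import load_fixture, percent_change
from saltlax.physiostats import round_half_away


def mean(table, treatment, indicator):
    return table.query("treatment == @treatment and indicator == @indicator")["mean"].iloc[0]


t1 = load_fixture("table1")
t2 = load_fixture("table2")

print("salt stress (S) vs control (CK), percent decrease:")
for ind in ("SLA", "Chl", "Pn", "Gs", "Ci", "Tr"):
    pct = percent_change(mean(t1, "CK", ind), mean(t1, "S", ind), "decrease")
    print(f"  {ind:>4}: {round_half_away(pct):>3}%")

print("lanthanum rescue (S+La0.75) vs S, percent increase:")
for ind in ("glycyrrhizic acid", "glycyrrhetinic acid", "liquiritin", "total flavonoids"):
    pct = percent_change(mean(t2, "S", ind), mean(t2, "S+La0.75", ind), "increase")
    print(f"  {ind:>20}: {round_half_away(pct):>4}%")
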