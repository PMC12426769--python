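"""Discretization schemes: where temperatures and equivalence ratios land.

Temperature uses 30 uniform 10 °C bins (−100 to 200 °C); reactant and
agent equivalence ratios use custom bins with narrow intervals around
the stoichiometries chemists actually use.
"""

from condrec import agent_amount_bins, reactant_amount_bins, temperature_bins

temp = temperature_bins()
react = reactant_amount_bins()
agent = agent_amount_bins()

print(f"temperature: {temp.n_bins} bins, reactant: {react.n_bins}, agent: {agent.n_bins}")

for t in (-78.0, 0.0, 25.0, 111.0):
    i = temp.assign(t)
    lo, hi = temp.interval(i)
    print(f"  {t:6.1f} °C -> bin {i:2d} [{lo:.0f}, {hi:.0f}) reported as {temp.representatives[i]:.0f} °C")

for eq in (1.0, 1.5, 2.0, 2.54):
    i = react.assign(eq)
    print(f"  reactant {eq:4.2f} eq -> bin {i:2d} {react.interval(i)} rep {react.representatives[i]}")

for eq in (0.03, 1.0, 20.0):
    i = agent.assign(eq)
    regime = "catalytic" if eq < 0.5 else "stoichiometric" if eq < 5 else "solvent-scale"
    print(f"  agent {eq:6.2f} eq -> bin {i:2d} ({regime})")
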