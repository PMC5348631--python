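"""Construct a participant-specific adaptive trial schedule.

Shows how a pretest discount rate turns into per-delay indifference
amounts and a symmetric six-rung amount ladder, and how the 216-trial
session is organized into condition blocks.
"""

import tagdisc as td

K_PRETEST = 0.03

print(f"pretest discount rate k = {K_PRETEST}/day  (immediate reference 20 EUR)")
print(f"{'delay (d)':>9} {'indifference (EUR)':>19}  ladder (EUR)")
for delay in (2, 7, 15, 32, 95, 190):
    a_star = td.indifference_amount(K_PRETEST, delay)
    ladder = td.build_amount_ladder(K_PRETEST, delay)
    print(f"{delay:9d} {a_star:19.2f}  {[round(float(a), 1) for a in ladder]}")

schedule = td.build_session(K_PRETEST, seed=3)
seq = schedule.trials.groupby("block_index")["condition"].first()
print(f"\nsession: {schedule.n_trials} trials in 6 blocks")
print("block order:", " ".join(seq))
print(schedule.trials.head(5).to_string(index=False))
print()
print("Amounts straddle each delay's indifference point symmetrically")
print("(clamped into 20.5-79.5 EUR, half-euro steps), so choices carry")
print("maximal information about the participant's discount rate; the")
print("two blocks of each condition are always adjacent.")
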