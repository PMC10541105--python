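"""Generate one session of the four-block odor-guided choice task.

Prints the block contingencies and the event stream of two example trials:
a long-delay trial (block 1) and a double-bolus trial (block 3).
"""

from posmtd.config import TaskConfig
from posmtd.state_spaces import DEFAULT_ALPHABET
from posmtd.task_simulator import SessionConfig, generate_session

session = generate_session(SessionConfig(
    task=TaskConfig(trials_per_block=65), seed=3, side_a_is_left=True))

print("block contingencies (side -> role):")
seen = set()
for tr in session.trials:
    key = (tr.block, tr.metadata["side"])
    if key not in seen:
        seen.add(key)
        print(f"  block {tr.block}: {tr.metadata['side']:5s} -> "
              f"{tr.metadata['contingency']}")

for pick in (lambda t: t.block == 1 and t.metadata["contingency"] == "long"
             and t.metadata["delay_s"] == 7,
             lambda t: t.block == 3 and t.metadata["n_boluses"] == 2):
    tr = next(t for t in session.trials if pick(t))
    print(f"\nblock {tr.block} trial {tr.trial_in_block} "
          f"({tr.metadata['contingency']}, delay {tr.metadata['delay_s']} s):")
    for name, step in sorted(tr.event_times.items(), key=lambda kv: kv[1]):
        print(f"  t = {step * 0.1:5.1f} s  {name}")
    print("  tagged analysis events:", dict(tr.metadata["event_tags"]))

print("\nEvery step between the listed events carries the empty observation;")
print("the symbol stream is what the learning agent actually sees.")
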