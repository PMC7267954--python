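"""Generate a counterbalanced emotional-conflict task sequence.

Builds the protocol-scale sequence (2 runs x 74 trials, 3-5 s jittered
ISI), shows the counterbalancing bookkeeping and the conflict-adaptation
coding, and writes a BIDS-style events table.
"""

from collections import Counter

from conflicticc import task_design as td

seq = td.generate_sequence(n_runs=2, trials_per_run=74, isi_range=(3, 5), seed=7)

print(f"total trials: {len(seq)}")
for run in (1, 2):
    trials = seq.run(run)
    congruent = sum(t.congruent for t in trials)
    happy = sum(t.face_emotion == "happy" for t in trials)
    labels = Counter(t.adaptation_label for t in trials)
    print(f"run {run}: {len(trials)} trials, {congruent} congruent / "
          f"{len(trials) - congruent} incongruent, {happy} happy faces")
    print(f"  adaptation cells: {dict(labels)}")
    print(f"  run duration: {td.run_duration(seq, run):.1f} s")

td.write_events(seq, "task_events.tsv")
print("wrote task_events.tsv (onset / duration / trial_type / isi_after)")

# The equal congruent/incongruent and happy/fear counts per run are exact
# by construction; the cC/cI/iC/iI cells are each guaranteed >= 10 per run
# so the conflict-adaptation (iI - cI) contrast stays estimable.
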