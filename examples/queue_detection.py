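"""Detecting ribosome queuing with the traffic simulator.

Three regimes on a 60-codon transcript: well-spaced launches (no
queuing), launches faster than a slow-codon cluster can drain (trailing
ribosomes queue and finish late), and a very slow 5' region (the first
ribosome still covers the start codon when the next one arrives).
"""

from ribocalc import simulate_transcript

fast, slow = 0.05, 0.5
dwell = [fast] * 60
dwell[35:45] = [slow] * 10  # ten-codon rare cluster, 5 s service time

for label, interval in [("relaxed", 6.0), ("overloaded", 4.0)]:
    res = simulate_transcript(dwell, initiation_interval=interval, n_ribosomes=4)
    times = ", ".join(f"{t:.2f}" for t in res.cumulative_times)
    print(f"{label:10s} I={interval:.1f} s -> class {res.klass}; "
          f"per-ribosome traversal times [s]: {times}")

blocked = simulate_transcript([2.0] * 10 + [fast] * 50, initiation_interval=1.0)
print(f"{'slow 5end':10s} I=1.0 s -> class {blocked.klass} "
      f"(attachment blocked, transcript rejected)")

print("\nclass 0: all ribosomes traverse in the same time;")
print("class 1: trailing ribosomes are delayed by the ribosome ahead;")
print("class 2: the initiation region never clears between launches.")
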