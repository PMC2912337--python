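"""Naive fixed-timestep ribosome-traffic simulator.

Independent oracle for the event-driven engine: time advances in steps of
``min(dwell) / 100``; at each step every attached ribosome runs down its
dwell clock and, once expired, advances one codon if the target codon is
not covered by the ribosome ahead (processed downstream-most first).  A
new ribosome attaches at the start codon at the first step boundary after
each multiple of the initiation interval, provided the previous ribosome
has cleared the footprint region; a failed attempt classifies the
transcript as 2 (blocked 5' end).
"""

from __future__ import annotations


def fixed_timestep_classify(dwell, initiation_interval, footprint=10, n_ribosomes=5):
    """Return (klass, cumulative_times) like the event-driven engine."""
    L = len(dwell)
    assert footprint < L
    dt = min(dwell) / 100.0
    pos: list[int] = []       # A-site codon (0-based), downstream first
    rem: list[float] = []     # remaining dwell at current codon
    start: list[float] = []
    cumulative: list[float] = []
    t = 0.0
    n_attached = 0
    max_t = (n_ribosomes + 1) * initiation_interval + 10 * sum(dwell) + 1.0
    while len(cumulative) < n_ribosomes:
        # attachment attempts due at or before t (downstream moves at the
        # same instant were processed in the previous iteration)
        while n_attached < n_ribosomes and n_attached * initiation_interval <= t + 1e-12:
            if pos and pos[-1] < footprint:
                return 2, cumulative
            pos.append(0)
            rem.append(dwell[0])
            start.append(n_attached * initiation_interval)
            n_attached += 1
        t += dt
        finished = 0
        for i in range(len(pos)):
            rem[i] -= dt
            if rem[i] <= 1e-12:
                ahead = pos[i - 1] if i > 0 else None
                if pos[i] == L - 1:
                    # release at the exact dwell expiry within this step
                    cumulative.append(t + rem[i] - start[i])
                    finished += 1  # only the leader can be at L-1
                elif ahead is None or ahead - pos[i] > footprint:
                    pos[i] += 1
                    # carry the undershoot so the clock does not drift
                    rem[i] += dwell[pos[i]]
                else:
                    # stalled: waiting accrues no dwell credit
                    rem[i] = 0.0
        for _ in range(finished):
            pos.pop(0)
            rem.pop(0)
            start.pop(0)
        if t > max_t:
            raise RuntimeError("oracle failed to terminate")
    tol = 3 * dt
    queued = any(abs(c - cumulative[0]) > tol for c in cumulative)
    return (1 if queued else 0), cumulative
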