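"""Brute-force trigger-event oracle: advance one second at a time.

Applies the entry/dwell definitions literally — presence starts at the
first contained instant, ENTRY fires after the confirmation period of
uninterrupted containment, DWELL on every dwell-interval anniversary of
presence start — sharing no scanning logic with the engine under test.
The continuity convention matches the engine's: between consecutive
samples the user is wherever the earlier sample said.
"""

from quitfence.geo import contains


def oracle_events(trace, fences, entry_s=300, dwell_s=10800, strict=True):
    """Return sorted (type, fence_id, timestamp) triples; timestamps must be ints."""
    events = []
    times = [int(s.timestamp) for s in trace]
    for fence in fences:
        flags = [contains(fence, s, strict) for s in trace]
        ps = None
        idx = 0
        for t in range(times[0], times[-1] + 1):
            while idx + 1 < len(times) and times[idx + 1] <= t:
                idx += 1
            if flags[idx]:
                if ps is None:
                    ps = t
                elapsed = t - ps
                if elapsed == entry_s:
                    events.append(("ENTRY", fence.id, t))
                elif elapsed > 0 and elapsed % dwell_s == 0:
                    events.append(("DWELL", fence.id, t))
            else:
                ps = None
    return sorted(events, key=lambda e: (e[2], e[1], e[0]))
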