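"""Shared independent oracles for the test suite."""

import numpy as np


def brute_force_dsb_count(positions, strands, eps=3.4, require_both=True):
    """Independent clustering oracle: connected components of the pairwise
    ≤eps distance graph; clusters need ≥2 points (isolated points are noise)
    and, optionally, both strand labels."""
    n = len(positions)
    if n == 0:
        return 0
    pos = np.asarray(positions, dtype=float)
    adj = (
        np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2) <= eps
    ) & ~np.eye(n, dtype=bool)
    seen = np.zeros(n, dtype=bool)
    count = 0
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comp = [u for u in comp if adj[u].any()]
        if len(comp) >= 2:
            labels = {int(strands[u]) for u in comp}
            if not require_both or labels == {0, 1}:
                count += 1
    return count
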