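"""Shared test utilities."""

import numpy as np


def topo_backward(out, seed_grad):
    """Backpropagate from ``out`` with an arbitrary gradient seed."""
    topo, seen, stack = [], set(), [(out, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))
    out.grad = np.asarray(seed_grad, out.data.dtype)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
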