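"""Naive reference implementation of the belief-propagation update.

This is a deliberately plain, line-by-line transcription of the published
update rules, written independently of the package's engine module and kept
free of any shared code.  It exists solely so the test suite can compare the
optimised engine against an unambiguous restatement of the maths:

  * integer value v in -4..4  ->  probability (5 + v) / 10
  * per informative parent Y:  P(Xi|Y) = e * P(Yi) + (1 - e) * (1 - P(Yi))
    with e the edge probability and P(Xi|Yd) = 1 - P(Xi|Yi)
  * prior-bearing posterior:   P + (1 - P) * sum(P * (c - 0.5)) / n
  * interactions-only posterior: mean(c)
  * final posterior = whichever lies furthest from 0.5 (tie -> prior-bearing)
  * clamp to [0.1, 0.9]; nodes with nonzero scenario priors never become
    less certain than their initial prior
  * after the last iteration, change = 10 * (p - 0.5)
"""


def oracle_predict(nodes, edges, priors, iterations=4):
    """Propagate a scenario through a signed network, the slow obvious way.

    nodes: sequence of labels; edges: {(parent, child): int strength};
    priors: {label: int in -4..4}; returns {label: float change}.
    """
    p = {}
    for node in nodes:
        v = priors.get(node, 0)
        p[node] = (5.0 + v) / 10.0
    pinned = {node: p[node] for node in nodes if priors.get(node, 0) != 0}

    for _ in range(iterations):
        new_p = {}
        for child in nodes:
            conditionals = []
            for parent in nodes:
                if (parent, child) not in edges:
                    continue
                if abs(p[parent] - 0.5) <= 1e-9:
                    continue  # no knowledge of a change in the parent
                e = (5.0 + edges[(parent, child)]) / 10.0
                c = e * p[parent] + (1.0 - e) * (1.0 - p[parent])
                conditionals.append(c)
            if not conditionals:
                new_p[child] = p[child]
                continue
            n = len(conditionals)
            prior = p[child]
            total = 0.0
            for c in conditionals:
                total += prior * (c - 0.5)
            post_a = prior + (1.0 - prior) * total / n
            post_b = sum(conditionals) / n
            post_a = min(0.9, max(0.1, post_a))
            post_b = min(0.9, max(0.1, post_b))
            # ties (within float noise) go to the prior-bearing candidate
            if abs(post_a - 0.5) >= abs(post_b - 0.5) - 1e-12:
                post = post_a
            else:
                post = post_b
            if child in pinned and abs(post - 0.5) < abs(pinned[child] - 0.5):
                post = pinned[child]
            new_p[child] = post
        p = new_p

    return {node: 10.0 * (p[node] - 0.5) for node in nodes}
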