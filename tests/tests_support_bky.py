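"""Reference two-stage adaptive step-up, written independently of the
package implementation (direct transcription of the procedure: stage-1
linear step-up at q/(1+q), null-count estimate, stage-2 step-up)."""

import numpy as np


def _step_up(p, level):
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= level * rank / m:
            kmax = rank
    reject[order[:kmax]] = True
    return reject


def bky_reference(p, q):
    p = np.asarray(p, dtype=float)
    m = len(p)
    q1 = q / (1.0 + q)
    r1 = int(_step_up(p, q1).sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return _step_up(p, q1 * m / (m - r1))
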