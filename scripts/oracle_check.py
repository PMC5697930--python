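"""Independent brute-force state-probability enumeration used by the
acceptance script as a cross-check; shares no code with the package's
partition-function routines."""

import itertools
import math


def brute_force_probabilities(model):
    rt = model.thermal_energy
    names = [d.name for d in model.domains]
    stabilities = [d.stability for d in model.domains]
    weights = {}
    for s in itertools.product((0, 1), repeat=len(names)):
        energy = 0.0
        for k in range(len(names)):
            if s[k] == 1:
                energy = energy - stabilities[k]
        for c in model.couplings:
            i = names.index(c.pair[0])
            j = names.index(c.pair[1])
            if s[i] == 1 and s[j] == 1:
                energy = energy - c.delta_g
        weights[s] = math.exp(-energy / rt)
    q = sum(weights.values())
    return {s: w / q for s, w in weights.items()}
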