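"""Independent brute-force oracles, deliberately sharing no code with the
package's energy/partition routines: every quantity is recomputed from first
principles (explicit loops over indicator vectors, energies assembled inline).
"""

import itertools
import math


def brute_force_probabilities(model):
    """State probabilities by direct enumeration; keys are indicator tuples."""
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


def brute_force_observables(model):
    """(activity, affinity) by direct enumeration; None when undefined."""
    probs = brute_force_probabilities(model)
    names = [d.name for d in model.domains]
    bind = [i for i, d in enumerate(model.domains) if d.is_binding]
    func = [i for i, d in enumerate(model.domains) if d.is_functional]
    affinity = activity = None
    if bind:
        affinity = sum(p for s, p in probs.items() if s[bind[0]] == 1)
        if func:
            activity = sum(
                p for s, p in probs.items() if s[bind[0]] == 1 and s[func[0]] == 1
            )
    return activity, affinity


def brute_force_nll(values, data, family):
    """Gaussian negative log-likelihood recomputed from brute-force ensembles."""
    ref_model = family.construct(family.reference).build(values)
    ref_act, ref_aff = brute_force_observables(ref_model)
    total = 0.0
    for name in data.constructs:
        row = data.frame.loc[name]
        if name == family.reference:
            pred_act, pred_aff = 1.0, 1.0
        else:
            act, aff = brute_force_observables(family.construct(name).build(values))
            pred_act, pred_aff = act / ref_act, aff / ref_aff
        total += 0.5 * ((pred_act - row["activity_rel"]) / row["activity_err"]) ** 2
        total += 0.5 * ((pred_aff - row["affinity_rel"]) / row["affinity_err"]) ** 2
    return total


def brute_force_grid_search(space, data, family):
    """Exhaustive per-point search; returns (best_params, best_objective)."""
    best = None
    best_vec = None
    for combo in itertools.product(*(a.values for a in space.axes)):
        values = dict(zip(space.names, combo))
        obj = brute_force_nll(values, data, family)
        if best is None or obj < best or (obj == best and combo < best_vec):
            best, best_vec = obj, combo
    return dict(zip(space.names, best_vec)), best
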