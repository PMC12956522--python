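"""Independent brute-force oracles used by the tests.

Deliberately naive (per-neuron scalar loops, exhaustive enumeration) and
written without reference to the package's vectorised implementations.
"""

import numpy as np


def scalar_lif_trace(v0, currents, alpha, v_th, v_reset, reset_mode, t_ref):
    """Per-neuron scalar LIF simulation; returns (voltages, spikes) lists."""
    v = float(v0)
    refr = 0
    vs, ss = [], []
    for current in currents:
        if refr > 0:
            refr -= 1
            spike = 0
        else:
            v_pre = (1.0 - alpha) * v + float(current)
            if v_pre >= v_th:
                spike = 1
                v = v_reset if reset_mode == "hard" else v_pre - v_th
                if t_ref > 0:
                    refr = t_ref
            else:
                spike = 0
                v = v_pre
        vs.append(v)
        ss.append(spike)
    return np.array(vs), np.array(ss)


def brute_force_sop(incoming_per_layer, fanouts):
    """SOP by explicit per-spike, per-synapse accumulation."""
    total = 0
    for counts, fanout in zip(incoming_per_layer, fanouts):
        for n_spikes in np.asarray(counts).ravel():
            for _ in range(int(n_spikes)):
                total += fanout
    return total


def exhaustive_pareto(a, e):
    """Non-dominated indices by pairwise comparison of (a, e), both maximised."""
    keep = []
    for i in range(len(a)):
        dominated = False
        for j in range(len(a)):
            if j == i:
                continue
            if (a[j] >= a[i] and e[j] >= e[i]
                    and (a[j] > a[i] or e[j] > e[i])):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


def enumerate_boundary(mask):
    """Boundary by explicit 4-neighbour enumeration; off-grid is outside."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    for i in range(rows):
        for j in range(cols):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                outside = not (0 <= ni < rows and 0 <= nj < cols) \
                    or not mask[ni, nj]
                if outside:
                    out[i, j] = True
                    break
    return out


def scalar_mlp_forward(weights, biases, x_spikes, alpha, v_th, v_reset,
                       reset_mode="hard", wrec=None, wrec_layer=None):
    """Pen-and-paper simulation of a dense spiking network (no normalisation
    or with identity normalisation), all loops scalar.

    ``weights[k]`` has shape [n_out, n_in]; the last layer is the readout.
    Returns mean output spikes per class.
    """
    T = len(x_spikes)
    n_layers = len(weights)
    v = [[0.0 + v_reset for _ in range(w.shape[0])] for w in weights]
    s_prev_layer = [[0.0] * w.shape[0] for w in weights]
    out_counts = [0.0] * weights[-1].shape[0]
    for t in range(T):
        inp = list(x_spikes[t])
        for k in range(n_layers):
            n_out = weights[k].shape[0]
            spikes = [0.0] * n_out
            for i in range(n_out):
                current = biases[k][i]
                for j in range(len(inp)):
                    current += weights[k][i][j] * inp[j]
                if wrec is not None and k == wrec_layer:
                    for j in range(n_out):
                        current += wrec[i][j] * s_prev_layer[k][j]
                v_pre = (1.0 - alpha) * v[k][i] + current
                if v_pre >= v_th:
                    spikes[i] = 1.0
                    v[k][i] = v_reset if reset_mode == "hard" else v_pre - v_th
                else:
                    v[k][i] = v_pre
            s_prev_layer[k] = spikes
            inp = spikes
        for i in range(len(out_counts)):
            out_counts[i] += inp[i]
    return np.array(out_counts) / T
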