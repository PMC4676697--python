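"""Independent Parratt-recursion reflectivity oracle.

Deliberately coded from the recursive formulation (bottom interface upward),
sharing nothing with the transfer-matrix implementation it cross-checks.
"""

import numpy as np


def parratt_reflectivity(fronting_sld, layers, backing_sld, backing_roughness, q):
    """R(Q) by Parratt recursion.

    ``layers``: sequence of (thickness, effective_sld, roughness) with the
    roughness belonging to the layer's substrate-side interface; SLDs in
    1e-6 Å⁻². Solvent penetration must already be mixed into the SLDs.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    slds = [fronting_sld] + [sld for _, sld, _ in layers] + [backing_sld]
    thick = [0.0] + [d for d, _, _ in layers] + [0.0]
    sigmas = [s for _, _, s in layers] + [backing_roughness]
    n = len(slds)

    kz = []
    for rho in slds:
        ksq = (q / 2.0) ** 2 - 4.0e-6 * np.pi * (rho - fronting_sld)
        kz.append(np.sqrt(ksq.astype(complex)))

    # start at the deepest interface (layer n-2 | backing), work upward
    r_next = np.zeros_like(kz[0])
    for j in range(n - 2, -1, -1):
        kj, kj1 = kz[j], kz[j + 1]
        fresnel = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * sigmas[j] ** 2)
        phase = np.exp(2j * kj1 * thick[j + 1])
        r_next = (fresnel + r_next * phase) / (1.0 + fresnel * r_next * phase)
    return np.abs(r_next) ** 2
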