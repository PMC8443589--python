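"""Seeded tabular fixtures: drug-decay series, expression matrices, panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mpskit.fixtures.render import lognormal_noise
from mpskit.fixtures.specs import DecaySpec, ExprSpec, PanelSpec
from mpskit.panels import PanelMatrix
from mpskit.pk import ConcentrationSeries


def gen_decay(spec: DecaySpec, analyte: str = "compound") -> tuple[ConcentrationSeries, float]:
    """First-order decay series ``c(t) = c0 * exp(-k t) * eps`` with
    lognormal multiplicative noise of the configured CV.

    Returns the series and the true elimination rate used to generate it.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sample_times_h, dtype=float)
    clean = spec.c0_uM * np.exp(-spec.k_per_h * times)
    eps = lognormal_noise(times.shape, spec.noise_cv, rng).astype(float)
    series = ConcentrationSeries(
        analyte=analyte, times_h=times, conc_uM=clean * eps, input_conc_uM=spec.c0_uM
    )
    return series, float(spec.k_per_h)


def gen_expression(spec: ExprSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2-scale expression matrix plus its generating truth table.

    Model per cell: baseline(gene) + group effect + plate offset + residual.
    The group effect (the configured signed log2 fold-change) applies to every
    non-reference group; the first group listed is the reference.  Plates are
    assigned round-robin across samples when no explicit assignment is given.

    Returns ``(matrix, truth)`` where ``matrix`` is genes x samples and
    ``truth`` has columns gene, log2fc, is_de.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    samples = spec.sample_ids()

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)

    if spec.batch_assignment is None:
        plates = {s: f"plate{(i % 2) + 1}" for i, s in enumerate(samples)}
    else:
        plates = {s: spec.batch_assignment.get(s, "plate1") for s in samples}
    plate_labels = sorted(set(plates.values()))
    plate_offset = {p: rng.normal(0.0, spec.batch_sd) if spec.batch_sd > 0 else 0.0
                    for p in plate_labels}

    effect = np.zeros(spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, lfc in spec.de_genes.items():
        effect[gene_index[g]] = lfc

    reference = spec.groups[0]
    data = np.empty((spec.n_genes, len(samples)))
    for j, s in enumerate(samples):
        grp = s.rsplit("_", 1)[0]
        col = baseline + (0.0 if grp == reference else effect) + plate_offset[plates[s]]
        if spec.residual_sd > 0:
            col = col + rng.normal(0.0, spec.residual_sd, size=spec.n_genes)
        data[:, j] = col

    matrix = pd.DataFrame(data, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": effect,
            "is_de": effect != 0.0,
        }
    )
    return matrix, truth


def gen_panel(spec: PanelSpec) -> PanelMatrix:
    """Biomarker panel with multiplicative noise and detection-limit flags.

    Cells whose realised concentration falls below the analyte's detection
    limit are flagged undetected (value retained for truth inspection).
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"{g}_{r + 1}" for g in spec.groups for r in range(spec.n_reps_per_group)]
    sample_map = {s: s.rsplit("_", 1)[0] for s in samples}

    values = np.zeros((len(spec.analytes), len(samples)))
    for i, a in enumerate(spec.analytes):
        for j, s in enumerate(samples):
            mean = spec.group_means.get((a, sample_map[s]), 0.0)
            noise = lognormal_noise((), spec.noise_cv, rng) if spec.noise_cv > 0 else 1.0
            values[i, j] = mean * float(noise)

    vdf = pd.DataFrame(values, index=list(spec.analytes), columns=samples)
    limits = np.array([spec.detection_limit.get(a, 0.0) for a in spec.analytes])
    detected = vdf.ge(limits, axis=0) & (vdf > 0)
    return PanelMatrix(values=vdf, detected=detected, sample_map=sample_map)
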