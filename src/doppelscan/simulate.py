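"""Synthetic microbiome count tables with class structure and injected
near-duplicate ("doppelganger") sample pairs.

The generative family is a standard overdispersed sparse-count emulator:
feature base abundances are log-normal (a few dominant taxa, a long tail of
rare ones), each sample draws counts multinomially from its class's mean
composition perturbed by per-sample multiplicative log-normal noise, library
sizes are gamma-distributed, and optional independent zero-inflation thins
the counts. Class signal enters as fold-changes on a chosen subset of
features (half enriched in cases, half depleted).

Doppelganger injection duplicates a donor sample up to per-feature
multiplicative noise and multinomial resampling, so zeros stay zeros and the
injected sample's library size matches its donor's.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .data_model import AbundanceTable, SampleLabels

__all__ = ["SimConfig", "InjectionSpec", "generate_table", "inject_doppelgangers"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-class count simulator.

    Defaults emulate a moderately deep 16S case/control cohort: 100 + 100
    samples over 500 taxa, ~5% of taxa differential at 3-fold, gamma library
    sizes around 20,000 reads, and mild zero-inflation.
    """

    n_case: int = 100
    n_control: int = 100
    n_features: int = 500
    n_differential: int = 25
    fold_change: float = 3.0
    base_abundance_log_mean: float = 0.0
    base_abundance_log_sd: float = 1.2
    library_size_mean: float = 20_000.0
    library_size_shape: float = 10.0
    zero_inflation: float = 0.05
    sample_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_differential <= self.n_features:
            raise ValueError("n_differential must be in [0, n_features]")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.library_size_mean <= 0 or self.library_size_shape <= 0:
            raise ValueError("library size parameters must be positive")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.sample_noise_sd < 0:
            raise ValueError("sample_noise_sd must be >= 0")


@dataclass(frozen=True)
class InjectionSpec:
    """Parameters of doppelganger-pair injection."""

    n_pairs: int = 5
    noise_sd: float = 0.05
    target_min_correlation: float = 0.99
    max_retries: int = 50
    resample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.target_min_correlation <= 1:
            raise ValueError("target_min_correlation must be in (0, 1]")
        if self.max_retries < 1:
            raise ValueError("max_retries must be positive")


def generate_table(
    config: SimConfig,
) -> tuple[AbundanceTable, SampleLabels, list[str]]:
    """Simulate a two-class count table.

    Returns the table, labels (classes ``case``/``control``), and the list of
    truly differential feature ids. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_features

    base = rng.lognormal(
        config.base_abundance_log_mean, config.base_abundance_log_sd, size=p
    )
    diff_idx = rng.choice(p, size=config.n_differential, replace=False)
    case_means = base.copy()
    half = config.n_differential // 2
    case_means[diff_idx[:half]] *= config.fold_change  # enriched in cases
    case_means[diff_idx[half:]] /= config.fold_change  # depleted in cases

    feature_ids = tuple(f"OTU{j:04d}" for j in range(p))
    differential = [feature_ids[j] for j in sorted(diff_idx)]

    n_total = config.n_case + config.n_control
    libsizes = np.maximum(
        1,
        np.round(
            rng.gamma(
                config.library_size_shape,
                config.library_size_mean / config.library_size_shape,
                size=n_total,
            )
        ).astype(int),
    )

    sample_ids = []
    label_map: dict[str, str] = {}
    counts = np.empty((n_total, p))
    for i in range(n_total):
        if i < config.n_case:
            sid, lab, means = f"case{i:03d}", "case", case_means
        else:
            sid, lab, means = f"ctrl{i - config.n_case:03d}", "control", base
        sample_ids.append(sid)
        label_map[sid] = lab
        noisy = means * rng.lognormal(0.0, config.sample_noise_sd, size=p)
        comp = noisy / noisy.sum()
        row = rng.multinomial(libsizes[i], comp).astype(float)
        if config.zero_inflation > 0:
            row *= rng.random(p) >= config.zero_inflation
        counts[i] = row

    table = AbundanceTable(tuple(sample_ids), feature_ids, counts, "counts")
    labels = SampleLabels(label_map, case_label="case")
    return table, labels, differential


def inject_doppelgangers(
    table: AbundanceTable,
    labels: SampleLabels,
    spec: InjectionSpec,
) -> tuple[AbundanceTable, SampleLabels, list[tuple[str, str]]]:
    """Append near-duplicate samples of randomly chosen same-class donors.

    Each injected sample is its donor's count vector scaled per-feature by
    ``exp(N(0, noise_sd^2))``, renormalized, and (by default) multinomially
    resampled to the donor's library size; regeneration is retried until the
    Pearson correlation between donor and copy proportions reaches
    ``target_min_correlation``. Donors are distinct; originals are untouched.

    Returns the augmented table, augmented labels, and the injected
    (donor_id, copy_id) pairs.
    """
    if spec.n_pairs == 0:
        return table, labels, []
    if table.mode != "counts":
        raise ValueError("injection operates on counts-mode tables")
    rng = np.random.default_rng(spec.seed)
    donor_pool = [s for s in table.sample_ids]
    if spec.n_pairs > len(donor_pool):
        raise ValueError(
            f"cannot inject {spec.n_pairs} pairs: only {len(donor_pool)} donors"
        )
    donors = [str(d) for d in rng.choice(donor_pool, size=spec.n_pairs, replace=False)]

    new_rows = []
    new_ids = []
    new_labels = dict(labels.labels)
    injected: list[tuple[str, str]] = []
    for k, donor in enumerate(donors):
        d = table.values[table.sample_index(donor)]
        lib = int(round(d.sum()))
        d_prop = d / d.sum()
        best_r, best_row = -np.inf, None
        for _ in range(spec.max_retries):
            noisy = d * np.exp(rng.normal(0.0, spec.noise_sd, size=d.size))
            if spec.resample:
                row = rng.multinomial(lib, noisy / noisy.sum()).astype(float)
            else:
                row = noisy
            row_sum = row.sum()
            if row_sum == 0:
                continue
            r = float(np.corrcoef(d_prop, row / row_sum)[0, 1])
            if r > best_r:
                best_r, best_row = r, row
            if r >= spec.target_min_correlation - 1e-12:
                break
        else:
            raise RuntimeError(
                f"could not reach correlation {spec.target_min_correlation} for donor "
                f"{donor!r} in {spec.max_retries} tries (best {best_r:.6f})"
            )
        copy_id = f"dop{k:03d}_{donor}"
        new_ids.append(copy_id)
        new_rows.append(best_row)
        new_labels[copy_id] = labels[donor]
        a, b = sorted((donor, copy_id))
        injected.append((a, b))

    values = np.vstack([table.values, np.array(new_rows)])
    out = AbundanceTable(
        table.sample_ids + tuple(new_ids), table.feature_ids, values, "counts"
    )
    return out, SampleLabels(new_labels, case_label=labels.case_label), injected
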