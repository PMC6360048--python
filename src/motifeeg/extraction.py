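"""Trial-level feature extraction into labeled feature tables.

Ties the per-trial extractors together over whole epoch sets: every trial
is band-decomposed once, benchmark (58) and/or motif (108) features are
computed, and per-subject individualized thresholds turn the 9-point
ratings into binary high/low labels for each affect dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark_features import (benchmark_feature_names,
                                 extract_benchmark_features)
from .classification import DIMENSIONS, individualized_threshold
from .graph_features import (GRAPH_SUBGROUPS, extract_motif_features,
                             motif_feature_names)
from .motif_connectivity import SyncConfig
from .signal_io import (BandDefinition, DEFAULT_BANDS, EpochSet, Montage,
                        band_decompose, reference_montage, subtract_baseline)

__all__ = ["FeatureTable", "feature_group_tags", "build_feature_table"]


@dataclass
class FeatureTable:
    """Trials x named-features matrix with group tags and binary labels.

    ``data`` holds one row per trial; ``labels`` has one binary column per
    affect dimension; ``groups`` maps each feature name to its
    ``(group, subgroup)`` tag (benchmark: power/ratio/entropy/asymmetry;
    motif: weighted_graph/unweighted_graph/small_world/dof/pe/dm);
    ``subjects`` records the originating subject per trial.
    """

    data: pd.DataFrame
    labels: pd.DataFrame
    groups: dict[str, tuple[str, str]] = field(default_factory=dict)
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if len(self.labels) != len(self.data):
            raise ValueError("labels/trials length mismatch")
        bad = set(self.labels.to_numpy().ravel()) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary, found {bad}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, group: str | None = None,
               subgroup: str | None = None) -> "FeatureTable":
        """Restrict columns to one group and/or subgroup tag."""
        keep = [name for name, (g, sg) in self.groups.items()
                if (group is None or g == group)
                and (subgroup is None or sg == subgroup)]
        return FeatureTable(
            data=self.data[keep], labels=self.labels,
            groups={k: self.groups[k] for k in keep},
            subjects=self.subjects)


def feature_group_tags(montage: Montage,
                       bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
                       ) -> dict[str, tuple[str, str]]:
    """(group, subgroup) tag for every benchmark and motif feature name."""
    tags: dict[str, tuple[str, str]] = {}
    for name in benchmark_feature_names(montage, bands):
        if name.startswith("power("):
            sub = "power"
        elif name.startswith("ratio("):
            sub = "ratio"
        elif name == "SE":
            sub = "entropy"
        else:
            sub = "asymmetry"
        tags[name] = ("benchmark", sub)
    for name in motif_feature_names(montage, bands):
        if name.startswith("PE("):
            sub = "pe"
        elif name.startswith("Dm("):
            sub = "dm"
        else:
            sub = GRAPH_SUBGROUPS[name.split("(")[0]]
        tags[name] = ("motif", sub)
    return tags


def _subject_labels(es: EpochSet) -> np.ndarray:
    cols = [individualized_threshold(es.ratings[:, d]).labels
            for d in range(len(DIMENSIONS))]
    return np.column_stack(cols)


def build_feature_table(epochsets: EpochSet | list[EpochSet],
                        montage: Montage | None = None,
                        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                        groups: tuple[str, ...] = ("benchmark", "motif"),
                        sync_cfg: SyncConfig = SyncConfig(),
                        lag: int = 1, n_null: int = 10, seed: int = 0,
                        apply_baseline: bool = True) -> FeatureTable:
    """Extract the requested feature groups for every trial of every subject.

    Baseline correction (when prestimulus matrices are present) precedes
    band decomposition; the decomposition is shared between the benchmark
    and motif extractors.  ``seed`` only randomizes the small-world null
    ensemble, deterministically per trial.
    """
    if isinstance(epochsets, EpochSet):
        epochsets = [epochsets]
    montage = montage or reference_montage()
    tags = feature_group_tags(montage, bands)
    rows, label_rows, subjects = [], [], []
    ss = np.random.SeedSequence(seed)
    trial_seeds = iter(ss.generate_state(
        sum(es.n_trials for es in epochsets)))
    for es in epochsets:
        if es.channel_names != montage.channel_names:
            raise ValueError("epoch set channels do not match montage")
        labels = _subject_labels(es)
        for t, trial in enumerate(es.trials):
            if apply_baseline and es.baselines is not None:
                trial = subtract_baseline(trial, es.baselines[t])
            band_epochs = band_decompose(trial, es.fs, bands)
            parts = []
            if "benchmark" in groups:
                parts.append(extract_benchmark_features(
                    trial, es.fs, montage, bands, band_epochs=band_epochs))
            if "motif" in groups:
                parts.append(extract_motif_features(
                    trial, es.fs, montage, bands, sync_cfg=sync_cfg,
                    lag=lag, n_null=n_null,
                    seed=int(next(trial_seeds)) % (2 ** 31),
                    band_epochs=band_epochs))
            rows.append(pd.concat(parts))
            label_rows.append(labels[t])
            subjects.append(es.subject_id)
    data = pd.DataFrame(rows).reset_index(drop=True)
    labels = pd.DataFrame(np.asarray(label_rows), columns=list(DIMENSIONS))
    return FeatureTable(
        data=data, labels=labels,
        groups={name: tags[name] for name in data.columns},
        subjects=np.asarray(subjects))
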