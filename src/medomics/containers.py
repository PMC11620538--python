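"""Core data containers shared by every analysis stage.

A study is represented by two objects:

* :class:`StudyFrame` — the epidemiologic backbone: one row per sample with
  an exposure, an outcome (continuous or binary), covariates, and a cohort
  label.
* :class:`MultiOmics` — an ordered collection of named omics layers, each a
  samples × features matrix, all sharing one sample index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class StudyFrame:
    """Per-sample exposure, outcome, covariates, and cohort label.

    Parameters
    ----------
    exposure : pd.Series
        Continuous exposure (e.g. prenatal blood mercury), indexed by sample id.
    outcome : pd.Series
        Continuous or binary outcome (e.g. serum CK-18), same index.
    covariates : pd.DataFrame
        Named covariate columns; categoricals allowed (dummy-coded on demand).
    cohort : pd.Series
        Categorical cohort/stratum label, same index.
    """

    exposure: pd.Series
    outcome: pd.Series
    covariates: pd.DataFrame
    cohort: pd.Series

    def __post_init__(self) -> None:
        idx = self.exposure.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        for name, obj in (
            ("outcome", self.outcome),
            ("covariates", self.covariates),
            ("cohort", self.cohort),
        ):
            if not obj.index.equals(idx):
                raise ValueError(f"{name} index does not match exposure index")

    @property
    def sample_ids(self) -> pd.Index:
        return self.exposure.index

    @property
    def n(self) -> int:
        return len(self.exposure)

    def design_matrix(self, covariates: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric covariate design (no intercept); categoricals dummy-coded
        with the lexicographically first level as reference."""
        if covariates is None:
            covariates = list(self.covariates.columns)
        cols = self.covariates[list(covariates)]
        if cols.shape[1] == 0:
            return pd.DataFrame(index=self.sample_ids)
        out = pd.get_dummies(cols, drop_first=True, dtype=float)
        return out.astype(float)

    def subset(self, ids) -> "StudyFrame":
        return StudyFrame(
            exposure=self.exposure.loc[ids],
            outcome=self.outcome.loc[ids],
            covariates=self.covariates.loc[ids],
            cohort=self.cohort.loc[ids],
        )


class MultiOmics:
    """Ordered, named omics layers sharing one sample index.

    Each layer is a samples × features :class:`pandas.DataFrame`; feature ids
    must be unique within a layer and sample ordering identical across layers.
    """

    def __init__(self, layers: Mapping[str, pd.DataFrame]):
        self._layers: dict[str, pd.DataFrame] = {}
        ref_index = pd.Index([]) if not layers else None
        for name, mat in layers.items():
            if mat.columns.has_duplicates:
                raise ValueError(f"layer {name!r}: duplicate feature ids")
            if ref_index is None:
                ref_index = mat.index
            elif not mat.index.equals(ref_index):
                raise ValueError(
                    f"layer {name!r}: sample index differs from first layer"
                )
            self._layers[name] = mat
        self._index = ref_index

    @property
    def sample_ids(self) -> pd.Index:
        return self._index

    @property
    def layer_names(self) -> list[str]:
        return list(self._layers)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self._layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def items(self):
        return self._layers.items()

    def concat(self, layers: Sequence[str] | None = None) -> pd.DataFrame:
        """Column-concatenate layers (early integration), prefixing feature
        ids with the layer name to keep them globally unique."""
        names = list(layers) if layers is not None else self.layer_names
        if not names:
            return pd.DataFrame(index=self._index)
        parts = []
        for name in names:
            part = self._layers[name].copy()
            part.columns = [f"{name}:{c}" for c in part.columns]
            parts.append(part)
        return pd.concat(parts, axis=1)

    def layer_of(self, prefixed_feature: str) -> tuple[str, str]:
        """Split a 'layer:feature' id produced by :meth:`concat`."""
        layer, _, feat = prefixed_feature.partition(":")
        return layer, feat

    def subset_features(self, keep: Mapping[str, Sequence[str]]) -> "MultiOmics":
        return MultiOmics(
            {name: self._layers[name][list(feats)] for name, feats in keep.items()}
        )

    def align_to(self, ids) -> "MultiOmics":
        missing = [s for s in ids if s not in self._index]
        if missing:
            raise ValueError(f"samples absent from omics layers: {missing[:5]}")
        return MultiOmics({name: mat.loc[ids] for name, mat in self._layers.items()})
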