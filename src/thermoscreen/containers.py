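"""Shared in-memory containers for the screening pipeline.

The pipeline moves three kinds of data between stages: a multi-sample SNP
genotype panel (``GenotypeMatrix``), a raw gene-by-sample count matrix with
its sample sheet (``CountMatrix``), and the nested factorial design of the
common-garden experiment (``ModelSpec``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing call

#: Canonical study layout: 3 localities x 2 stages x 2 temperatures x 3 replicates.
LOCALITIES = ("TAT", "CAT", "FAR")
STAGES = (36, 42)
TEMPERATURES = (20, 25)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for sites x samples with per-call quality/depth.

    Genotypes are alt-allele dosages in {0, 1, 2} with ``MISSING`` (-1) for
    no-calls. Arrays are sites-major: shape ``(n_sites, n_samples)``.
    """

    samples: list[str]
    chrom: np.ndarray          # (n_sites,) str — transcript/contig id
    pos: np.ndarray            # (n_sites,) int, 1-based
    ref: np.ndarray            # (n_sites,) str
    alt: np.ndarray            # (n_sites,) str; comma-joined if multi-allelic
    gt: np.ndarray             # (n_sites, n_samples) int8
    gq: np.ndarray             # (n_sites, n_samples) int
    dp: np.ndarray             # (n_sites, n_samples) int
    site_qual: np.ndarray      # (n_sites,) float

    def __post_init__(self) -> None:
        n_sites = len(self.pos)
        n_samples = len(self.samples)
        if self.gt.shape != (n_sites, n_samples):
            raise ValueError(
                f"genotype array shape {self.gt.shape} does not match "
                f"{n_sites} sites x {n_samples} samples"
            )
        if len(set(self.samples)) != n_samples:
            raise ValueError("duplicate sample ids")
        if n_sites and self.pos.min() < 1:
            raise ValueError("positions must be 1-based (>= 1)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_biallelic(self) -> np.ndarray:
        """Boolean mask of sites with a single alternate allele."""
        return np.array(["," not in a for a in self.alt], dtype=bool)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            gt=self.gt[idx],
            gq=self.gq[idx],
            dp=self.dp[idx],
            site_qual=self.site_qual[idx],
        )

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        col = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            gt=self.gt[:, col],
            gq=self.gq[:, col],
            dp=self.dp[:, col],
            site_qual=self.site_qual,
        )

    def site_ids(self) -> np.ndarray:
        """``chrom:pos`` identifiers, unique per site in a biallelic panel."""
        return np.array([f"{c}:{p}" for c, p in zip(self.chrom, self.pos)])


@dataclass
class ModelSpec:
    """Nested factorial design: log mu = l_i + d_ij + t_ik.

    ``l_i`` is a per-locality intercept, ``d_ij`` the developmental-stage
    effect within locality i, and ``t_ik`` the temperature effect within
    locality i. Identifiability comes from reference-level coding inside
    each locality: d_{i,ref_stage} = 0 and t_{i,ref_temp} = 0, so the
    coefficient ``t_{i,25}`` is directly the within-locality 25-vs-20
    temperature contrast on the natural-log scale.
    """

    localities: tuple[str, ...] = LOCALITIES
    stages: tuple[int, ...] = STAGES
    temperatures: tuple[int, ...] = TEMPERATURES
    ref_stage: int = 36
    ref_temp: int = 20

    def __post_init__(self) -> None:
        if self.ref_stage not in self.stages:
            raise ValueError("reference stage not among stages")
        if self.ref_temp not in self.temperatures:
            raise ValueError("reference temperature not among temperatures")
        if len(self.temperatures) < 2:
            raise ValueError("design needs >= 2 temperatures")

    def coef_names(self) -> list[str]:
        names = [f"l_{i}" for i in self.localities]
        names += [
            f"d_{i}{j}" for i in self.localities for j in self.stages if j != self.ref_stage
        ]
        names += [
            f"t_{i}{k}"
            for i in self.localities
            for k in self.temperatures
            if k != self.ref_temp
        ]
        return names

    def design_matrix(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Build the constrained design matrix for a sample sheet.

        ``samples`` needs columns ``locality``, ``stage``, ``temperature``.
        Rows follow the sample-sheet order; columns follow :meth:`coef_names`.
        """
        for col in ("locality", "stage", "temperature"):
            if col not in samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        unknown = set(samples["locality"]) - set(self.localities)
        if unknown:
            raise ValueError(f"samples map to unknown localities: {sorted(unknown)}")
        X = pd.DataFrame(0.0, index=samples.index, columns=self.coef_names())
        for sid, row in samples.iterrows():
            i, j, k = row["locality"], int(row["stage"]), int(row["temperature"])
            X.loc[sid, f"l_{i}"] = 1.0
            if j != self.ref_stage:
                X.loc[sid, f"d_{i}{j}"] = 1.0
            if k != self.ref_temp:
                X.loc[sid, f"t_{i}{k}"] = 1.0
        return X

    def temperature_coefs(self, locality: str) -> list[str]:
        """Names of the temperature coefficients for one locality."""
        if locality not in self.localities:
            raise ValueError(f"unknown locality {locality!r}")
        return [
            f"t_{locality}{k}" for k in self.temperatures if k != self.ref_temp
        ]

    def sample_sheet(
        self, n_replicates: int = 3, drop_samples: tuple[str, ...] = ()
    ) -> pd.DataFrame:
        """Full-factorial sample sheet, one row per sample.

        Sample ids follow the ``{LOC}{TEMP}G{STAGE}_r{REP}`` convention
        (e.g. ``TAT20G42_r1``); ``drop_samples`` removes named samples,
        mirroring exclusion of a flagged outlier replicate.
        """
        rows = []
        for loc in self.localities:
            for stage in self.stages:
                for temp in self.temperatures:
                    for rep in range(1, n_replicates + 1):
                        rows.append(
                            {
                                "sample_id": f"{loc}{temp}G{stage}_r{rep}",
                                "locality": loc,
                                "stage": stage,
                                "temperature": temp,
                                "replicate": rep,
                            }
                        )
        sheet = pd.DataFrame(rows).set_index("sample_id")
        missing = set(drop_samples) - set(sheet.index)
        if missing:
            raise ValueError(f"drop_samples not in design: {sorted(missing)}")
        return sheet.drop(index=list(drop_samples))


@dataclass
class CountMatrix:
    """Raw integer gene x sample counts plus the sample sheet."""

    counts: pd.DataFrame            # genes x samples, non-negative integers
    samples: pd.DataFrame           # indexed by sample_id: locality/stage/temperature/replicate
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self._validated:
            return
        if list(self.counts.columns) != list(self.samples.index):
            if set(self.counts.columns) != set(self.samples.index):
                raise ValueError("count columns and sample sheet disagree")
            self.samples = self.samples.loc[list(self.counts.columns)]
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("negative counts")
        if vals.size and not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        self._validated = True

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_samples(self, sample_ids: list[str]) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s not in set(sample_ids)]
        return CountMatrix(self.counts[keep], self.samples.loc[keep])
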