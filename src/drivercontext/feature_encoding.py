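"""Numeric feature representations of mutation neighborhoods.

Three representations are supported, mirroring the seven experiment cells
(OHE; Count k=2,3,4; TF-IDF k=2,3,4):

* one-hot encoding of the 2n flanking bases (the center wild-type base is
  not one-hot encoded), giving exactly ``8n + 2`` columns once the
  chromosome and substitution-type ordinals are appended;
* overlapping k-mer counts against a vocabulary fitted on training data;
* TF-IDF weighting of those counts, either with the textbook formula
  ``freq * ln(N / d)`` (``paper_formula``) or the scikit-learn convention
  of smoothed idf plus row-wise L2 normalization (``smoothed_l2``, the
  default).

Vocabulary fitting is strictly a training-time operation: transforming new
documents ignores k-mers absent from the fitted vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mutation_io import Neighborhood

logger = logging.getLogger("drivercontext")

#: One-hot slot order for each flanking base.  "A" -> <1,0,0,0>,
#: "G" -> <0,1,0,0>, "C" -> <0,0,1,0>, "T" -> <0,0,0,1>.
OHE_BASE_ORDER = ("A", "G", "C", "T")

REPRESENTATIONS = ("OHE", "CV", "TF")
KMER_SIZES = (2, 3, 4)


@dataclass(frozen=True)
class EncodingSpec:
    """Which representation to use for a given window size."""

    representation: str          # OHE | CV | TF
    window_size: int
    k: int | None = None
    tfidf_variant: str = "smoothed_l2"   # or "paper_formula"

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        if self.representation == "OHE":
            if self.k is not None:
                raise ValueError("k is not applicable to OHE")
        elif self.k is None:
            raise ValueError(f"k is required for {self.representation}")
        if self.tfidf_variant not in ("paper_formula", "smoothed_l2"):
            raise ValueError(f"unknown tfidf_variant {self.tfidf_variant!r}")

    @property
    def name(self) -> str:
        return self.representation if self.k is None else f"{self.representation}(k={self.k})"


@dataclass
class FeatureMatrix:
    """Dense numeric features with stable row keys and column names."""

    row_keys: list[str]
    column_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_keys), len(self.column_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.row_keys)} rows / {len(self.column_names)} columns"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column names must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_keys, columns=self.column_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="key")

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="key"))


@dataclass
class KmerVocabulary:
    """Distinct k-mers of the fitting corpus with their document frequencies."""

    k: int
    terms: list[str]
    document_frequency: np.ndarray
    n_documents: int
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.document_frequency = np.asarray(self.document_frequency, dtype=int)
        self._index = {t: i for i, t in enumerate(self.terms)}
        if len(self._index) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")
        if np.any(self.document_frequency < 1) or np.any(
            self.document_frequency > self.n_documents
        ):
            raise ValueError("document frequencies must lie in [1, n_documents]")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._index


def decompose_kmers(sequence: str, k: int) -> list[str]:
    """Overlapping k-mers of ``sequence``, left to right, duplicates kept."""
    if k < 2 or k > len(sequence):
        raise ValueError(f"k must satisfy 2 <= k <= len(sequence), got {k}")
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


def fit_vocabulary(corpus: Sequence[Sequence[str]], k: int) -> KmerVocabulary:
    """Learn the sorted distinct k-mers and their document frequencies."""
    if len(corpus) == 0:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    df: dict[str, int] = {}
    for doc in corpus:
        for term in set(doc):
            if len(term) != k:
                raise ValueError(f"term {term!r} does not have length k={k}")
            df[term] = df.get(term, 0) + 1
    terms = sorted(df)
    return KmerVocabulary(
        k=k,
        terms=terms,
        document_frequency=np.array([df[t] for t in terms]),
        n_documents=len(corpus),
    )


def count_vectorize(
    corpus: Sequence[Sequence[str]], vocab: KmerVocabulary,
    row_keys: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Term-count matrix against a fitted vocabulary.

    Terms not in the vocabulary contribute nothing (the transform-only
    discipline for test data).
    """
    counts = np.zeros((len(corpus), len(vocab)), dtype=float)
    index = vocab._index
    for j, doc in enumerate(corpus):
        for term in doc:
            i = index.get(term)
            if i is not None:
                counts[j, i] += 1
    keys = list(row_keys) if row_keys is not None else [str(j) for j in range(len(corpus))]
    return FeatureMatrix(keys, list(vocab.terms), counts)


def tfidf_vectorize(
    corpus: Sequence[Sequence[str]], vocab: KmerVocabulary,
    variant: str = "smoothed_l2",
    row_keys: Sequence[str] | None = None,
) -> FeatureMatrix:
    """TF-IDF matrix against a fitted vocabulary.

    ``paper_formula`` scores cell (j, i) as ``freq_ij * ln(N / d_i)`` with no
    row normalization.  ``smoothed_l2`` applies the scikit-learn convention,
    ``idf = ln((1 + N) / (1 + d)) + 1`` followed by row-wise L2 normalization.
    """
    fm = count_vectorize(corpus, vocab, row_keys=row_keys)
    d = vocab.document_frequency.astype(float)
    if np.any(d <= 0):
        raise ValueError("vocabulary has a term with zero document frequency")
    if variant == "paper_formula":
        idf = np.log(vocab.n_documents / d)
        fm.values = fm.values * idf
    elif variant == "smoothed_l2":
        # idf depends only on the *fitted* (N, d), so test-time transforms
        # never touch test statistics.
        idf = np.log((1.0 + vocab.n_documents) / (1.0 + d)) + 1.0
        weighted = fm.values * idf
        norms = np.linalg.norm(weighted, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        fm.values = weighted / norms
    else:
        raise ValueError(f"unknown tfidf variant {variant!r}")
    return fm


def one_hot_encode(neighborhoods: Sequence[Neighborhood]) -> FeatureMatrix:
    """One-hot matrix with exactly ``8n + 2`` columns.

    Each of the 2n flanking bases gets a 4-slot indicator block (order
    A, G, C, T); the center wild-type base is not encoded.  The chromosome
    code and substitution-type code are appended as two ordinal columns.
    """
    if not neighborhoods:
        raise ValueError("no neighborhoods to encode")
    n = neighborhoods[0].window_size
    if any(nb.window_size != n for nb in neighborhoods):
        raise ValueError("all neighborhoods must share one window size")
    offsets = [i - n for i in range(2 * n + 1) if i != n]   # -n..-1, +1..+n
    columns = [
        f"flank{off:+d}_{base}" for off in offsets for base in OHE_BASE_ORDER
    ] + ["chromosome", "substitution_type"]
    values = np.zeros((len(neighborhoods), len(columns)))
    base_slot = {b: i for i, b in enumerate(OHE_BASE_ORDER)}
    for j, nb in enumerate(neighborhoods):
        for col_block, off in enumerate(offsets):
            base = nb.sequence[off + n]
            values[j, 4 * col_block + base_slot[base]] = 1
        values[j, -2] = nb.chromosome_code
        values[j, -1] = nb.substitution_type
    keys = [nb.mutation.key for nb in neighborhoods]
    return FeatureMatrix(keys, columns, values)


def encode_neighborhoods(
    neighborhoods: Sequence[Neighborhood],
    spec: EncodingSpec,
    vocab: KmerVocabulary | None = None,
) -> tuple[FeatureMatrix, KmerVocabulary | None]:
    """Encode neighborhoods per ``spec``.

    For k-mer representations, ``vocab=None`` fits a new vocabulary on the
    given corpus (training); passing a fitted vocabulary transforms only
    (test).  The chromosome and substitution-type ordinals are always
    appended.  Returns the matrix and the vocabulary used (None for OHE).
    """
    if not neighborhoods:
        raise ValueError("no neighborhoods to encode")
    if any(nb.window_size != spec.window_size for nb in neighborhoods):
        raise ValueError("neighborhood window sizes disagree with the encoding spec")
    if spec.representation == "OHE":
        return one_hot_encode(neighborhoods), None
    corpus = [decompose_kmers(nb.sequence, spec.k) for nb in neighborhoods]
    keys = [nb.mutation.key for nb in neighborhoods]
    if vocab is None:
        vocab = fit_vocabulary(corpus, spec.k)
    if spec.representation == "CV":
        fm = count_vectorize(corpus, vocab, row_keys=keys)
    else:
        fm = tfidf_vectorize(corpus, vocab, variant=spec.tfidf_variant, row_keys=keys)
    extra = np.array(
        [[nb.chromosome_code, nb.substitution_type] for nb in neighborhoods], dtype=float
    )
    fm = FeatureMatrix(
        fm.row_keys,
        fm.column_names + ["chromosome", "substitution_type"],
        np.hstack([fm.values, extra]),
    )
    return fm, vocab


def assemble_features(
    encoded: FeatureMatrix,
    descriptive: pd.DataFrame | None = None,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Concatenate sequence features with a descriptive genomic feature table.

    ``descriptive`` is indexed by mutation key.  Returns the combined matrix
    and a boolean missing-mask (True where a cell needs imputation: rows
    absent from the table, or NaN cells within it).  With no table the input
    is returned unchanged with an all-False mask.
    """
    if descriptive is None:
        return encoded, np.zeros_like(encoded.values, dtype=bool)
    desc_cols = list(map(str, descriptive.columns))
    clash = set(desc_cols) & set(encoded.column_names)
    if clash:
        logger.warning("renaming %d clashing descriptive column(s) with prefix", len(clash))
        desc_cols = [f"desc_{c}" if c in clash else c for c in desc_cols]
    aligned = descriptive.reindex(encoded.row_keys)
    desc_values = aligned.to_numpy(dtype=float)
    combined = FeatureMatrix(
        encoded.row_keys,
        encoded.column_names + desc_cols,
        np.hstack([encoded.values, desc_values]),
    )
    mask = np.zeros_like(combined.values, dtype=bool)
    mask[:, len(encoded.column_names):] = np.isnan(desc_values)
    return combined, mask


def enumerate_representations(window_size: int, tfidf_variant: str = "smoothed_l2") -> list[EncodingSpec]:
    """The seven experiment representations for one window size."""
    specs = [EncodingSpec("OHE", window_size)]
    for rep in ("CV", "TF"):
        for k in KMER_SIZES:
            specs.append(EncodingSpec(rep, window_size, k=k, tfidf_variant=tfidf_variant))
    return specs
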