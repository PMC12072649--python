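"""Dual molecular representation: Morgan fingerprints + standardized descriptors.

Each drug is featurized as (i) a binary circular-substructure (Morgan)
fingerprint, radius 2, folded to 2048 bits by default, and (ii) a vector of
2-D physicochemical descriptors, z-scored column-wise against the library
(dataset-wise moments). SMILES are canonicalized before fingerprinting so
equivalent notations collide; unparsable structures are skipped and listed
in a rejects table rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; rejects are reported ourselves

#: fixed, documented descriptor order: rdkit's 2-D descriptor list, registry order
DEFAULT_DESCRIPTORS = tuple(name for name, _ in Descriptors._descList)


def featurize_drug(
    smiles: str,
    n_bits: int = 2048,
    radius: int = 2,
    descriptor_set: tuple[str, ...] = DEFAULT_DESCRIPTORS,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Fingerprint + raw descriptor vector for one structure.

    Returns ``(fingerprint uint8[n_bits], descriptors float[len(set)],
    canonical_smiles)``. Raises ``ValueError`` for unparsable SMILES.
    Non-finite descriptor values (rare numeric overflows) are mapped to 0.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        fp[bit] = 1
    lookup = dict(Descriptors._descList)
    desc = np.array([lookup[name](mol) for name in descriptor_set], dtype=float)
    bad = ~np.isfinite(desc)
    if bad.any():
        logger.warning("non-finite descriptor(s) %s for %s set to 0",
                       [descriptor_set[i] for i in np.flatnonzero(bad)][:3], canonical)
        desc[bad] = 0.0
    return fp, desc, canonical


def featurize_library(
    library: pd.DataFrame,
    n_bits: int = 2048,
    radius: int = 2,
    descriptor_set: tuple[str, ...] = DEFAULT_DESCRIPTORS,
):
    """Featurize a drug library TSV frame (columns drug_id, smiles).

    Returns ``(drug_ids, fingerprints, descriptors, rejects)`` where
    ``rejects`` is a DataFrame of (drug_id, smiles, reason) for structures
    that failed to parse.
    """
    ids, fps, descs, rejects = [], [], [], []
    for drug_id, smiles in zip(library["drug_id"], library["smiles"]):
        try:
            fp, desc, canonical = featurize_drug(smiles, n_bits, radius, descriptor_set)
        except ValueError as exc:
            logger.warning("skipping %s: %s", drug_id, exc)
            rejects.append((drug_id, smiles, str(exc)))
            continue
        logger.debug("%s canonical SMILES: %s", drug_id, canonical)
        ids.append(drug_id)
        fps.append(fp)
        descs.append(desc)
    fp_mat = np.array(fps, dtype=np.uint8) if fps else np.zeros((0, n_bits), np.uint8)
    d_mat = np.array(descs) if descs else np.zeros((0, len(descriptor_set)))
    rej = pd.DataFrame(rejects, columns=["drug_id", "smiles", "reason"])
    return ids, fp_mat, d_mat, rej


@dataclass
class DescriptorScaler:
    """Column-wise z-scoring with dataset-wise moments.

    Zero-variance columns map to 0 (constant descriptors are
    uninformative). ``library_hash`` records the fitted matrix for
    provenance.
    """

    mean: np.ndarray
    std: np.ndarray
    library_hash: str = ""
    _scaler: StandardScaler = field(default=None, repr=False)

    @classmethod
    def fit(cls, descriptor_matrix: np.ndarray) -> "DescriptorScaler":
        x = np.asarray(descriptor_matrix, dtype=float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError("scaler fitting needs a 2-D matrix with >= 2 drugs")
        sk = StandardScaler().fit(x)
        digest = hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()[:16]
        return cls(mean=sk.mean_.copy(), std=np.sqrt(sk.var_), library_hash=digest, _scaler=sk)

    def transform(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        vec = d.ndim == 1
        if vec:
            d = d[None, :]
        if d.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"descriptor width {d.shape[1]} does not match scaler width {self.mean.shape[0]}"
            )
        if self._scaler is not None:
            out = self._scaler.transform(d)
        else:
            scale = np.where(self.std == 0.0, 1.0, self.std)
            out = (d - self.mean) / scale
        return out[0] if vec else out


def fit_scaler(descriptor_matrix: np.ndarray) -> DescriptorScaler:
    return DescriptorScaler.fit(descriptor_matrix)


def apply_scaler(scaler: DescriptorScaler, d: np.ndarray) -> np.ndarray:
    return scaler.transform(d)
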