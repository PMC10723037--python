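"""End-to-end glue: records + embeddings -> attributed graphs -> predictions.

Normalization statistics for the embedding block are fitted on the
designated training set only and travel with the trained ensemble.
"""

from __future__ import annotations

import numpy as np

from gtbind.graph import build_graph, DEFAULT_K, DEFAULT_PE_DIM, SPATIAL_DIM
from gtbind.node_features import (
    DSSP_DIM,
    assemble_node_features,
    dssp_feature_group,
    fit_minmax_stats,
    minmax_normalize,
)


def featurize_record(record, embedding, norm_stats, k=DEFAULT_K,
                     pe_dim=DEFAULT_PE_DIM, dssp_path=None,
                     sphere_points: int = 100, complete=False,
                     zero_spatial=False):
    """One protein -> ProteinGraph with assembled node features."""
    emb = minmax_normalize(embedding, norm_stats)
    dssp = dssp_feature_group(record, dssp_path=dssp_path,
                              sphere_points=sphere_points)
    nfm = assemble_node_features(emb, dssp, norm_stats=norm_stats)
    return build_graph(record, node_features=nfm, k=k, pe_dim=pe_dim,
                       complete=complete, zero_spatial=zero_spatial)


def featurize_dataset(records, embeddings, norm_stats=None, k=DEFAULT_K,
                      pe_dim=DEFAULT_PE_DIM, sphere_points: int = 100,
                      complete=False, zero_spatial=False):
    """All proteins -> (ids, graphs, labels, norm_stats).

    When ``norm_stats`` is None the min/max statistics are fitted on the
    embeddings of ``records`` (i.e. treat this set as training data).
    """
    if norm_stats is None:
        norm_stats = fit_minmax_stats([embeddings[r.id] for r in records])
    ids, graphs, labels = [], [], []
    for rec in records:
        g = featurize_record(rec, embeddings[rec.id], norm_stats, k=k,
                             pe_dim=pe_dim, sphere_points=sphere_points,
                             complete=complete, zero_spatial=zero_spatial)
        ids.append(rec.id)
        graphs.append(g)
        labels.append(None if rec.labels is None else rec.labels)
    return ids, graphs, labels, norm_stats


def feature_dims(embed_dim: int, pe_dim: int = DEFAULT_PE_DIM):
    """(input_dim, edge_dim) for a given embedding width."""
    return embed_dim + DSSP_DIM, SPATIAL_DIM + pe_dim
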