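"""Adapter for transformer protein language models (optional heavy path).

The toolkit's featurization treats per-residue embedders as pluggable;
this module holds the adapter for ProtTrans-style encoder models.  It is
only imported when ``torch`` and ``transformers`` are installed — every
test and default pipeline uses the deterministic physicochemical fallback
instead, so no model download is ever required.
"""

from __future__ import annotations

import numpy as np

from .records import SequenceRecord


class ProtTransEmbedder:
    """Mean-poolable per-residue embeddings from a ProtTrans encoder.

    Parameters
    ----------
    model_name:
        HuggingFace model id (default the X5 encoder half).
    layer:
        Which hidden layer to read per-residue states from; -1 is the
        final layer.  Exposed because the optimal layer is task-dependent.
    """

    tag = "prottrans-x5"

    def __init__(self, model_name: str = "Rostlab/prot_t5_xl_half_uniref50-enc", layer: int = -1):
        import torch
        from transformers import T5EncoderModel, T5Tokenizer

        self._torch = torch
        self._tokenizer = T5Tokenizer.from_pretrained(model_name, do_lower_case=False)
        self._model = T5EncoderModel.from_pretrained(model_name).eval()
        self._layer = layer
        self.dim = self._model.config.d_model

    def per_residue(self, seq: SequenceRecord) -> np.ndarray:
        spaced = " ".join(seq.residues)
        tokens = self._tokenizer(spaced, return_tensors="pt")
        with self._torch.no_grad():
            states = self._model(**tokens, output_hidden_states=True).hidden_states
        # drop the trailing special token; one row per residue
        return states[self._layer][0, : len(seq.residues)].cpu().numpy()
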