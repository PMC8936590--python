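# neuroevent

Joint extraction of neuroimaging research events — triggers, typed argument
roles and argument attributes — from article sentences, for building
research-provenance records.

The package covers the full pipeline:

- **schema** — the event type system (6 event categories, 9 argument
  categories, 3 attribute categories), the two per-sentence annotation
  encodings (BIO element tags and trigger-centric link rows), tab-separated
  corpus I/O, event validation, and mapping of extracted events to a
  PROV-JSON-style provenance document.
- **bootstrap** — tokenizer, per-category gazetteer dictionaries, and
  rule-based mention extraction for corpus building (trigger + two
  admissible arguments in a sentence; a Deactivate trigger + one brain-area
  argument suffices).
- **features** — per-token input vectors `[v_w, v_c, v_t]`: a word
  embedding (25-d by default, loadable from a GloVe/word2vec text file or
  derived from a seed), a 7-value one-hot case feature, and a
  one-dimensional terminology-dictionary label index.
- **model** — the joint network: stacked BiLSTM encoder, per-token element
  scorer with a linear-chain CRF over the 37 BIO tags, and a multi-label
  head-selection layer over the 18 relation labels with threshold decoding.
  Implemented on a small internal reverse-mode autodiff engine
  (`neuroevent.autodiff`) over NumPy — no deep-learning framework needed.
- **adversarial** — free adversarial training: each minibatch is replayed K
  times, the input-embedding gradient of each step is reused to move an
  L2-bounded perturbation, and the optimizer steps on the combined
  clean + perturbed loss; the epoch budget is divided by K.
- **evaluation** — strict P/R/F1 for element spans, relation arcs and whole
  events (strict/relaxed), plus the stratified fivefold few-shot protocol
  (train on one fifth, test on four).
- **synthetic** — a seeded generator of fully annotated corpora (one
  mention per sentence, schema-valid role fills, attributes adjacent to
  their arguments, distractor tokens, configurable category mix defaulting
  to 24/4/35/20/8/9%), so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic corpus + dictionaries + gold mentions
neuroevent synth --out-dir data --n 600 --seed 1

# rule-based bootstrap of an annotated corpus from raw sentences
neuroevent bootstrap --dict-dir data/dicts --in sentences.txt --out corpus.tsv

# train the joint model (omit --no-adv for adversarial training)
neuroevent train --corpus data/corpus.tsv --dict-dir data/dicts \
    --out model --epochs 200 --alpha 0.01 --free-k 3

# extract events from raw sentences; optionally emit provenance JSON
neuroevent predict --model model --in sentences.txt --out events.tsv \
    --prov provenance.json

# score predictions against gold annotations
neuroevent eval --gold corpus.tsv --pred events.tsv --report report.json
```

Corpus files are UTF-8, tab-separated, one token per line
(`position  word  bio_tag  role_label  [p1,p2,...]`), blank line between
sentences. Dictionary directories hold one `<CATEGORY>.txt` per category,
one term per line.

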