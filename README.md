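# apneaebr

Subject-specific detection of sleep-apnea events from two-channel EEG,
based on inter-band energy ratios of the five canonical EEG frequency
bands and a cosine-distance K-nearest-neighbour classifier.

Pipeline (per subject):

1. **Average** the two EEG channels (C3-A2, C4-A1) sample-wise to reduce noise.
2. **Frame** the averaged signal into non-overlapping 10 s frames; label a
   frame *apnea* when it lies entirely inside an annotated apnea interval
   and *non-apnea* when it is at least a guard distance (default 30 s) from
   every event; other frames are excluded. All apnea frames are kept and an
   equal number of non-apnea frames is subsampled (seeded).
3. **Preprocess** each frame: subtract the mean, normalise to unit maximum
   absolute amplitude.
4. **Decompose** into delta (0.25–4 Hz), theta (4–8), alpha (8–12),
   sigma (12–16) and beta (16–40 Hz) signals by brick-wall filtering in the
   FFT domain (half-open bin assignment, so band energies add exactly).
5. **Featurize**: band energies `E_p = Σ x_p[n]²` and the ten ordered
   inter-band ratios `R_pq = E_p/E_q` (delta-theta … sigma-beta); a reduced
   set is the first five ratios.
6. **Classify** with a from-first-principles KNN (euclidean / cityblock /
   cosine / correlation distances, deterministic tie rules) under
   leave-one-out or seeded (stratified) M-fold cross-validation.
7. **Evaluate**: confusion matrix, sensitivity/specificity/accuracy (%),
   Mann–Whitney ROC-AUC, the geometrical separability index (fraction of
   points whose nearest neighbour shares their label), and mean / sample-SD /
   IQR aggregates over subjects.

A seeded synthetic generator (`apneaebr.synthetic`) produces two-channel
recordings plus annotation schedules in which apnea segments shift energy
from low to high bands, so the entire chain is testable without clinical
data. Recordings are read/written as 16-bit EDF (a built-in minimal
implementation) or delimited text; annotations are 3-column TSV
(`onset_s  duration_s  label`).

## CLI

```sh
# synthetic recording + annotations (EDF + TSV + config echo)
apneaebr simulate --out sim/ --duration 1200 --n-events 10 --seed 7

# balanced per-frame feature matrix (TSV)
apneaebr features --recording sim/recording.edf \
    --annotations sim/annotations.tsv --out features.tsv --subject-id s1

# cross-validated evaluation report (CSV/JSON, per-subject + aggregates)
apneaebr evaluate features.tsv --out report/ --k 5 --distance cosine --cv loo
apneaebr evaluate features.tsv --out sweep/ --sweep distance

# feature-quality index only
apneaebr gsi features.tsv --metric euclidean

# metrics report from externally produced prediction files
apneaebr report predictions.tsv --out external_report.csv
```

Exit codes: 0 ok, 1 user/config error, 2 data error.

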