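"""Cross-validate the spectrum classifier on the 2000-spectrum dataset.

Builds the labelled set of STFT magnitude spectra (1000 click frames,
1000 noise frames), augments it with bin-wise random gains within
+/-3 dB, and reports mean stratified 5-fold cross-validation accuracy.
"""

import warnings

from finclick.detect import kfold_accuracy
from finclick.simulate import augment_spectra, generate_spectra_dataset

warnings.filterwarnings("ignore", category=FutureWarning)

spectra = generate_spectra_dataset(2000, 0.5, seed=1)
augmented = augment_spectra(spectra, max_db=3.0, copies=1, seed=2)
print(f"{len(spectra)} spectra -> {len(augmented)} after augmentation")

acc = kfold_accuracy(augmented, k=5, seed=3)
print(f"mean 5-fold CV accuracy: {100 * acc:.2f}%")
print("(the reference detector this emulates reports 98.7% on its "
      "2000-spectrum set)")
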