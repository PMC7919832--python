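"""Detect NBHF clicks in a synthetic recording and count them per minute.

Renders 60 s of 576 kHz audio containing click trains at 15-25 dB
in-band SNR, trains the SVM spectrum classifier on labelled synthetic
spectra, and runs the full chain: high-pass filter -> STFT -> frame
classification -> click events -> click density and train segmentation.
"""

import warnings

from finclick.detect import (DetectorConfig, click_density, detect_clicks,
                             segment_trains, train_classifier)
from finclick.simulate import (TrainProcess, generate_click_times,
                               generate_spectra_dataset, render_recording)

warnings.filterwarnings("ignore", category=FutureWarning)

config = DetectorConfig()
print("training the click/noise spectrum classifier ...")
spectra = generate_spectra_dataset(600, 0.5, seed=1)
model = train_classifier(spectra, seed=5, config=config)

process = TrainProcess(trains_per_minute=12, clicks_per_train=(5, 10),
                       snr_range_db=(15, 25))
clicks = generate_click_times(process, 60.0, seed=2)
clip, truth = render_recording(clicks, 60.0, seed=3)
print(f"rendered 60 s with {len(truth)} planted clicks")

events = detect_clicks(clip, model, config)
density = click_density(events, clip.duration)
trains = segment_trains(events)

print(f"detected {len(events)} click events "
      f"({100 * len(events) / len(truth):.1f}% of planted count)")
print(f"click density: {density.click_count.iloc[0]} clicks in minute 0")
print(f"click trains (>=5 clicks, ICI <= 200 ms): {len(trains)}")
if trains:
    t = trains[0]
    print(f"  first train: {len(t.clicks)} clicks, "
          f"median ICI {1000 * sorted(t.icis)[len(t.icis) // 2]:.0f} ms")
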