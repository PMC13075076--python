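"""Train the four classifier families on a subject-held-out split.

Uses a medium synthetic study, splits by participant (no subject in
both partitions), trains LDA / linear SVM / Gaussian NB / the
SCG-trained shallow ANN on the 2-class LL-LR task and on the 6-class
task, and prints held-out accuracy: more commands means lower accuracy.
"""

import numpy as np

import tonguemi as tm
from tonguemi.classify import ClassifierSpec, make_scheme

config = tm.SimulationConfig(n_subjects=8, trials_per_command_per_session=6)
study = tm.simulate_study(config, seed=21)
features = tm.build_feature_matrix(tm.preprocess_study(study))

train, test = tm.split_by_participant(features, ratio=0.7, seed=21)
print(f"train subjects: {sorted(map(str, set(train.subjects)))}")
print(f"test subjects:  {sorted(map(str, set(test.subjects)))}")

for name in ("LL-LR", "LL-LR-CL-CR-LU-LD"):
    scheme = make_scheme(name)
    tr = train.filter_commands(scheme.commands)
    te = test.filter_commands(scheme.commands)
    print(f"\n{scheme.n_classes}-class task ({name}), "
          f"{te.n_trials} held-out trials; chance = "
          f"{100 / scheme.n_classes:.1f}%")
    for family in tm.FAMILIES:
        model = tm.train_classifier(tr, ClassifierSpec(family), scheme,
                                    seed=21)
        acc = 100 * np.mean(model.predict(te) == te.y)
        print(f"  {family:4s} test accuracy {acc:5.1f}%")
print("\nAccuracy on unseen subjects drops as the command set grows — "
      "the central difficulty of multi-command motor-imagery BCIs.")
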