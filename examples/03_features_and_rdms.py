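"""CNN features and per-child RDMs: how the RDM score captures adaptation.

Drawings are rasterized (presented strokes black, produced strokes blue),
the blue ink is recolored black, the presented layer is dropped, and the
image is fed through a VGG-style backbone.  A child's 6x6 RDM holds the
Pearson distances d = 1 - corr between the fc7 features of their six
drawings; its mean off-diagonal entry is the RDM score.
"""
import numpy as np

from drawrsa import FeatureExtractor, make_test_backbone, simulate_cohort, simulate_drawing
from drawrsa.cohort import ChildAgent, STYLES
from drawrsa.rsa import child_rdm, rdm_score

net = make_test_backbone(seed=0)
extractor = FeatureExtractor(net)

bundle = simulate_cohort(1, rng=np.random.default_rng(0))
stimuli = [d.stimulus for d in bundle.drawings[:6]]


def completer(alpha: float, name: str, motif_seed: int) -> ChildAgent:
    weights = {s: 0.0 for s in STYLES}
    weights["complete"] = 1.0
    return ChildAgent(name, 60, alpha, weights, motif_seed, aq_propensity=0.3)


print("mean RDM score over 12 simulated children per adaptation level:")
for alpha in (0.0, 0.3, 0.9):
    scores = []
    for k in range(12):
        agent = completer(alpha, f"a{alpha}-{k}", motif_seed=k)
        rng = np.random.default_rng(1000 + k)
        drawings = [
            simulate_drawing(agent, s, rng, drawing_id=f"{agent.child_id}-{i}")
            for i, s in enumerate(stimuli)
        ]
        scores.append(rdm_score(child_rdm(drawings, extractor, layer="fc7")))
    print(f"  alpha = {alpha:.1f}: {np.mean(scores):.4f}")

print("\nAn alpha=0 agent repeats its motif on every stimulus, so all pairwise "
      "distances -- and the score -- collapse to 0.  Adaptive agents draw "
      "differently on different stimuli and score high; the score saturates "
      "at high alpha because canonical completions of related stimuli "
      "resemble each other.")
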