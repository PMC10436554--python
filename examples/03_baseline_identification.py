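"""Baseline person identification: can an SVM tell subjects apart from a
single movement's 256-sample vectors?  (The premise the translation
experiment builds on.)
"""

from crossmove.classify import SvmSearchSpace, evaluate, fit_svm, make_splits, SplitPlan
from crossmove.pipeline import ExperimentConfig, simulate_trials

config = ExperimentConfig(
    n_subjects=5,
    trials_per_domain={"walking": 60, "running": 60, "writing": 60},
    locomotion_scaling="per_trial",
    seed=3,
)
trials = simulate_trials(config)

# keep the demonstration quick: a reduced cost grid
space = SvmSearchSpace(cost_exponent_start=-3, cost_exponent_stop=5,
                       cost_exponent_step=1.0)

for domain in ("walking", "running", "writing"):
    if domain == "writing":
        data = trials[domain]
    else:
        from crossmove.preprocess import MovementVector, scale_unit_interval
        data = [MovementVector(values=scale_unit_interval(vec), domain=domain,
                               subject_id=sid, condition=cond,
                               source_trial_id=tid)
                for tid, sid, cond, vec in trials[domain]]
    split = make_splits(data, SplitPlan(fraction_gan_train=0.8,
                                        fraction_heldout=0.2, seed=1))
    model, chosen = fit_svm(split["gan_train"], space, seed=0)
    report = evaluate(model, split["heldout"],
                      [t.subject_id for t in split["gan_train"]],
                      task=f"baseline_{domain}", chosen=chosen)
    print(f"{domain:8s}: F1={report.f1:5.1f}%  accuracy={report.accuracy:5.1f}%"
          f"  ZRB={report.zrb:4.1f}%  kernel={chosen['kernel']}"
          f"  (n_train={report.n_train}, n_test={report.n_test})")

print("\nF1 far above the zero-rule baseline means each movement carries a"
      " clear individual signature — the premise for cross-movement transfer.")
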