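{
  "comment": "Published maximum-likelihood fits of the exponential-floor growth models, per bacterial kingdom. lnL_model is the profile log-likelihood of the fitted decay model; lnL_null is that of the constant (no generation-time effect) model on the same species.",
  "fits": [
    {
      "response": "n_rrn",
      "kingdom": "Bacillati",
      "alpha": 9.000380,
      "beta": 0.011936,
      "gamma": null,
      "lnL_model": -19.5164,
      "lnL_null": -25.8209,
      "p": 0.000384
    },
    {
      "response": "n_rrn",
      "kingdom": "Pseudomonadati",
      "alpha": 8.863043,
      "beta": 0.010691,
      "gamma": null,
      "lnL_model": -18.9248,
      "lnL_null": -26.0992,
      "p": 0.000152
    },
    {
      "response": "n_trna",
      "kingdom": "Bacillati",
      "alpha": 51.377406,
      "beta": 0.018713,
      "gamma": 45.392728,
      "lnL_model": -36.4670,
      "lnL_null": -151.0943,
      "p": 0.0
    },
    {
      "response": "n_trna",
      "kingdom": "Pseudomonadati",
      "alpha": 157.323365,
      "beta": 0.056354,
      "gamma": 40.954750,
      "lnL_model": -131.4144,
      "lnL_null": -475.6256,
      "p": 0.0
    }
  ]
}
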