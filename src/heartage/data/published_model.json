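{
  "resource_version": "1.0",
  "description": "Published gender-specific heart-age model constants: per-output drift coefficients theta, quadratic-age regression matrices beta (rows: y1, y2; columns: intercept, age, age^2), shared inverse noise covariance lambda_inv, prior scale sigma_a (years), and the logistic composite-score coefficient vectors gamma1/gamma2.",
  "sigma_a": 7.5,
  "output_ids": ["y1", "y2"],
  "gender_codes": {"male": 1, "female": 2},
  "theta": {
    "1": [0.170889, 0.265498],
    "2": [0.142849, 0.245966]
  },
  "beta": {
    "1": [
      [-5.951124, 0.133771, -0.000538],
      [-10.382251, 0.210635, -0.001508]
    ],
    "2": [
      [-4.880738, 0.072246, -0.00052],
      [-7.993616, 0.092820, -0.00220]
    ]
  },
  "lambda_inv": [
    [4.649546, -0.064033],
    [-0.064033, 0.519129]
  ],
  "gamma1": [-33.0669357, -0.007471284, 0.0524961, -3.977162174, -0.75406667, 0.295048301, 5.607131563],
  "gamma2": [-5.561987914, 3.278798871, 1.482313958, -2.6315664, 0.090181799, 0.048045487, 1.426993361]
}
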