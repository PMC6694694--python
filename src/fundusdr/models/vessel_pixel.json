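{
  "feature_names": [
    "red",
    "green",
    "blue",
    "lineness",
    "anisotropy",
    "green_minus_local"
  ],
  "mean": [
    149.95081,
    71.613346,
    37.532028,
    16.23512572285179,
    12.763847397306856,
    -4.88366344000008
  ],
  "scale": [
    24.836478863644295,
    24.114511495863173,
    11.9744517288774,
    12.72465001789979,
    9.858884491098005,
    20.176437902675836
  ],
  "coef": [
    4.733487856585796,
    -5.727044515462196,
    -1.2933038770741914,
    -0.4393312084939139,
    1.5779636705612212,
    -0.366031378767384
  ],
  "intercept": -2.1401328219641576,
  "classes": [
    "not",
    "vessel"
  ],
  "version": "1",
  "metadata": {
    "seed": 0,
    "n_train": 500000,
    "task": "vessel_pixel",
    "n_scenes": 20
  }
}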