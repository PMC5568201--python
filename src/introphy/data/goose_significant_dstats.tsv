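genus	P1	P2	P3	D	Z
Branta	Barnacle Goose	Cackling Goose	Canada Goose	0.087	4.322
Branta	Barnacle Goose	Cackling Goose	Red-breasted Goose	0.146	6.022
Branta	Barnacle Goose	Cackling Goose	Black Brent	0.094	3.516
Branta	Barnacle Goose	Canada Goose	Red-breasted Goose	0.1	4.037
Branta	Barnacle Goose	Hawaii Goose	Red-breasted Goose	0.094	4.192
Branta	Barnacle Goose	Black Brent	Red-breasted Goose	0.073	3.022
Anser	Lesser White-fronted Goose	Greater White-fronted Goose	Pink-footed Goose	0.126	6.116
Anser	Taiga Bean Goose	Greater White-fronted Goose	Pink-footed Goose	0.09	4.413
Anser	Pink-footed Goose	Greater White-fronted Goose	Emperor Goose	0.088	3.701
Anser	Tundra Bean Goose	Greater White-fronted Goose	Emperor Goose	0.079	3.383
Anser	Taiga Bean Goose	Greater White-fronted Goose	Emperor Goose	0.128	5.457
Anser	Greylag Goose	Greater White-fronted Goose	Emperor Goose	0.079	3.537
Anser	Taiga Bean Goose	Greater White-fronted Goose	Bar-headed Goose	0.083	3.470
Anser	Greater White-fronted Goose	Lesser White-fronted Goose	Swan Goose	0.114	5.279
Anser	Pink-footed Goose	Lesser White-fronted Goose	Swan Goose	0.15	6.821
Anser	Tundra Bean Goose	Lesser White-fronted Goose	Swan Goose	0.16	8.15
Anser	Taiga Bean Goose	Lesser White-fronted Goose	Swan Goose	0.173	8.385
Anser	Greater White-fronted Goose	Lesser White-fronted Goose	Ross' Goose	0.104	5.325
Anser	Pink-footed Goose	Lesser White-fronted Goose	Ross' Goose	0.12	5.421
Anser	Tundra Bean Goose	Lesser White-fronted Goose	Ross' Goose	0.103	4.682
Anser	Taiga Bean Goose	Lesser White-fronted Goose	Ross' Goose	0.083	3.93
Anser	Swan Goose	Lesser White-fronted Goose	Ross' Goose	0.103	3.984
Anser	Emperor Goose	Lesser White-fronted Goose	Ross' Goose	0.102	4.51
Anser	Greater White-fronted Goose	Lesser White-fronted Goose	Snow Goose	0.165	7.336
Anser	Pink-footed Goose	Lesser White-fronted Goose	Snow Goose	0.174	7.032
Anser	Tundra Bean Goose	Lesser White-fronted Goose	Snow Goose	0.157	7.053
Anser	Taiga Bean Goose	Lesser White-fronted Goose	Snow Goose	0.137	6.224
Anser	Swan Goose	Lesser White-fronted Goose	Snow Goose	0.156	6.525
Anser	Greylag Goose	Lesser White-fronted Goose	Snow Goose	0.086	4.054
Anser	Emperor Goose	Lesser White-fronted Goose	Snow Goose	0.14	6.007
Anser	Pink-footed Goose	Lesser White-fronted Goose	Emperor Goose	0.076	3.164
Anser	Tundra Bean Goose	Lesser White-fronted Goose	Emperor Goose	0.07	3.0
Anser	Taiga Bean Goose	Lesser White-fronted Goose	Emperor Goose	0.12	5.419
Anser	Greylag Goose	Lesser White-fronted Goose	Emperor Goose	0.078	3.472
Anser	Taiga Bean Goose	Pink-footed Goose	Bar-headed Goose	0.082	3.436
Anser	Greater White-fronted Goose	Greylag Goose	Ross' Goose	0.087	3.719
Anser	Pink-footed Goose	Greylag Goose	Ross' Goose	0.107	4.496
Anser	Tundra Bean Goose	Greylag Goose	Ross' Goose	0.086	3.408
Anser	Swan Goose	Greylag Goose	Ross' Goose	0.084	3.049
Anser	Emperor Goose	Greylag Goose	Ross' Goose	0.163	6.67
Anser	Greater White-fronted Goose	Greylag Goose	Snow Goose	0.072	3.055
Anser	Pink-footed Goose	Greylag Goose	Snow Goose	0.091	3.416
Anser	Emperor Goose	Greylag Goose	Snow Goose	0.139	5.59
Anser	Emperor Goose	Tundra Bean Goose	Ross' Goose	0.078	3.692
Anser	Emperor Goose	Tundra Bean Goose	Snow Goose	0.074	3.317
Anser	Emperor Goose	Taiga Bean Goose	Ross' Goose	0.139	6.346
Anser	Emperor Goose	Taiga Bean Goose	Snow Goose	0.139	6.655
Anser	Taiga Bean Goose	Greylag Goose	Bar-headed Goose	0.09	4.059
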