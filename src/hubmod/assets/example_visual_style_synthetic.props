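# Synthetic Cytoscape Vizmap visual style (original stand-in asset).
# Edge colours follow the correlation ramp used by this package:
# strong negative -> red, none -> yellow, strong positive -> green,
# with a colour-blind-safe blue/grey/orange alternative below.
# Import in Cytoscape via File > Import > Vizmap Property File.
edgeAppearanceCalculator.default.defaultEdgeColor=255,255,0
edgeAppearanceCalculator.default.defaultEdgeLineType=SOLID
edgeAppearanceCalculator.default.defaultEdgeLineWidth=2.0
edgeColorCalculator.CorrelationRamp.class=cytoscape.visual.calculators.GenericEdgeColorCalculator
edgeColorCalculator.CorrelationRamp.mapping.boundaryvalues=3
edgeColorCalculator.CorrelationRamp.mapping.bv0.domainvalue=-1.0
edgeColorCalculator.CorrelationRamp.mapping.bv0.equal=255,0,0
edgeColorCalculator.CorrelationRamp.mapping.bv1.domainvalue=0.0
edgeColorCalculator.CorrelationRamp.mapping.bv1.equal=255,255,0
edgeColorCalculator.CorrelationRamp.mapping.bv2.domainvalue=1.0
edgeColorCalculator.CorrelationRamp.mapping.bv2.equal=0,255,0
edgeColorCalculator.CorrelationRamp.mapping.controller=correlation
edgeColorCalculator.CorrelationRamp.mapping.interpolator=LinearNumberToColorInterpolator
edgeColorCalculator.CorrelationRampColorBlind.class=cytoscape.visual.calculators.GenericEdgeColorCalculator
edgeColorCalculator.CorrelationRampColorBlind.mapping.boundaryvalues=3
edgeColorCalculator.CorrelationRampColorBlind.mapping.bv0.domainvalue=-1.0
edgeColorCalculator.CorrelationRampColorBlind.mapping.bv0.equal=0,114,178
edgeColorCalculator.CorrelationRampColorBlind.mapping.bv1.domainvalue=0.0
edgeColorCalculator.CorrelationRampColorBlind.mapping.bv1.equal=153,153,153
edgeColorCalculator.CorrelationRampColorBlind.mapping.bv2.domainvalue=1.0
edgeColorCalculator.CorrelationRampColorBlind.mapping.bv2.equal=230,159,0
edgeColorCalculator.CorrelationRampColorBlind.mapping.controller=correlation
edgeColorCalculator.CorrelationRampColorBlind.mapping.interpolator=LinearNumberToColorInterpolator
nodeAppearanceCalculator.default.defaultNodeFillColor=211,211,211
nodeAppearanceCalculator.default.defaultNodeShape=ellipse
nodeAppearanceCalculator.default.defaultNodeSize=40.0
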