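# The 15 most documented insular regions with representative centroid
# coordinates (decimal degrees) for geographic network layouts downstream.
# Coordinates are indicative region centroids, not GIS delimitations.
- {region: "Africa Atlantic", lat: -15.0, lon: -8.0}
- {region: "Asian Coast", lat: 25.0, lon: 120.0}
- {region: "East Indies", lat: -2.0, lon: 115.0}
- {region: "Indo-Burma", lat: 12.0, lon: 98.0}
- {region: "Japan", lat: 36.0, lon: 138.0}
- {region: "Madagascar", lat: -19.0, lon: 47.0}
- {region: "Mediterranean Basin", lat: 38.0, lon: 15.0}
- {region: "New Caledonia", lat: -21.5, lon: 165.5}
- {region: "New Zealand", lat: -41.0, lon: 174.0}
- {region: "North America Pacific", lat: 35.0, lon: -122.0}
- {region: "Papua New Guinea", lat: -6.5, lon: 147.0}
- {region: "Philippines", lat: 12.0, lon: 122.0}
- {region: "Polynesia and Micronesia", lat: -15.0, lon: -150.0}
- {region: "South America Pacific", lat: -20.0, lon: -75.0}
- {region: "West Indies", lat: 18.0, lon: -70.0}
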