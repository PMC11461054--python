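{
  "type": "FeatureCollection",
  "name": "hotspot_regions",
  "description": "Hotspot region boundaries used for daily-geolocation assignment. NB and WEB are box approximations of previously published basin hotspots; Med is a basin box from the Strait of Gibraltar (-5.61 E) extended east to 36 E; NOR is a simplified Norwegian EEZ outline; Canaries follows the stated 24-35 N, 21-9 W extent. All are user-replaceable with a GeoJSON of the same schema.",
  "features": [
    {
      "type": "Feature",
      "properties": {"name": "Med"},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[
          [-5.61, 30.0], [36.0, 30.0], [36.0, 46.0], [-5.61, 46.0], [-5.61, 30.0]
        ]]
      }
    },
    {
      "type": "Feature",
      "properties": {"name": "NOR"},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[
          [1.8, 57.0], [7.0, 56.0], [10.8, 57.5], [10.0, 59.0], [17.0, 65.0],
          [31.0, 69.5], [36.0, 72.0], [16.0, 74.0], [0.0, 66.0], [-2.0, 62.0],
          [1.8, 57.0]
        ]]
      }
    },
    {
      "type": "Feature",
      "properties": {"name": "NB"},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[
          [-52.0, 37.0], [-36.0, 37.0], [-36.0, 47.0], [-52.0, 47.0], [-52.0, 37.0]
        ]]
      }
    },
    {
      "type": "Feature",
      "properties": {"name": "WEB"},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[
          [-24.0, 42.0], [-9.0, 42.0], [-9.0, 52.0], [-24.0, 52.0], [-24.0, 42.0]
        ]]
      }
    },
    {
      "type": "Feature",
      "properties": {"name": "Canaries"},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[
          [-21.0, 24.0], [-9.0, 24.0], [-9.0, 35.0], [-21.0, 35.0], [-21.0, 24.0]
        ]]
      }
    }
  ]
}
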